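"""Download-free synthetic datasets with the statistical structure the
classifier assumes.

The generator emulates what the real chimera datasets look like to the
model: a panel of ~21-nt miRNAs; positive target sites carrying a planted
complement of the miRNA seed (nucleotides 2-8) — by default together with
a 3'-supplementary complementary block, as ligated chimeras typically show
pairing beyond the bare seed — embedded in random context inside chimeras
of 60-110 nt that are then padded to 110; and pseudo-negative chimeras
drawn from annotated transcript regions (3'UTR : 5'UTR : ORF at 7 : 2 : 1)
through the same pseudo-site sampler used for real data.
``mutation_rate`` degrades the planted complement base-by-base, tuning
task difficulty.

Two fixture choices keep the planted signal representable by a
fixed-weight convolutional network (the module's purpose is a dataset on
which a *working* training pipeline demonstrably learns): the miRNA panel
is small (8 by default), so the network can memorize each miRNA's
complement motif rather than having to compute complementarity as a
relation; and the planted match sits near the 5' end of the site
(ligation junctions flank the bound region), bounding its positional
jitter.  With an unbounded panel or free match placement the task is not
learnable by this architecture and the fixture could not separate a
working pipeline from a broken one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chimera_builder import (
    BASES,
    Chimera,
    NegativeGenConfig,
    chimeras_to_table,
    concatenate_chimera,
    generate_pad,
    sample_negative_sites,
    split_dataset,
)
from .exceptions import ValidationError
from .sequence_io import (
    CHIMERA_LENGTH,
    DatasetTable,
    RegionInterval,
    SequenceRecord,
)

_RC = {"A": "U", "U": "A", "G": "C", "C": "G"}


def reverse_complement(seq: str) -> str:
    return "".join(_RC[b] for b in reversed(seq))


@dataclass
class SynthConfig:
    """Study conditions for the synthetic fixture (see module docstring)."""

    n_mirnas: int = 8
    mirna_length: int = 21
    n_transcripts: int = 40
    region_lengths: tuple[int, int, int] = (200, 900, 400)  # UTR5, ORF, UTR3
    n_pos: int = 2500
    n_neg: int = 2500
    seed_match_mode: str = "seed_plus_3prime"  # or "seed_2_8"
    mutation_rate: float = 0.05
    min_chimera_length: int = 60
    max_site_offset: int = 12  # planted match starts within this many nt of the site 5' end
    seed: int = 0

    def __post_init__(self):
        if min(self.n_mirnas, self.mirna_length, self.n_transcripts) <= 0:
            raise ValidationError("counts must be positive")
        if not 0.0 <= self.mutation_rate <= 0.3:
            raise ValidationError("mutation_rate must be in [0, 0.3]")
        if self.seed_match_mode not in ("seed_2_8", "seed_plus_3prime"):
            raise ValidationError(f"unknown seed_match_mode {self.seed_match_mode!r}")


def _random_seq(length: int, rng: np.random.Generator) -> str:
    return "".join(np.asarray(list(BASES))[rng.integers(0, 4, size=length)])


def gen_mirnas(config: SynthConfig, rng: np.random.Generator) -> list[SequenceRecord]:
    """Uniform-random miRNA panel with unique ids syn-mir-1..n."""
    return [
        SequenceRecord(f"syn-mir-{i + 1}", _random_seq(config.mirna_length, rng))
        for i in range(config.n_mirnas)
    ]


def gen_transcripts(
    config: SynthConfig, rng: np.random.Generator
) -> tuple[list[SequenceRecord], list[RegionInterval]]:
    """Random transcripts laid out 5'UTR + ORF + 3'UTR, with a BED-like
    region sidecar partitioning each transcript."""
    u5, orf, u3 = config.region_lengths
    records, regions = [], []
    for i in range(config.n_transcripts):
        tid = f"syn-tx-{i + 1}"
        records.append(SequenceRecord(tid, _random_seq(u5 + orf + u3, rng)))
        regions.extend(
            [
                RegionInterval(tid, 0, u5, "UTR5"),
                RegionInterval(tid, u5, u5 + orf, "ORF"),
                RegionInterval(tid, u5 + orf, u5 + orf + u3, "UTR3"),
            ]
        )
    return records, regions


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    out = []
    for b in seq:
        if rng.random() < rate:
            out.append(BASES[(BASES.index(b) + int(rng.integers(1, 4))) % 4])
        else:
            out.append(b)
    return "".join(out)


def planted_match(mirna_seq: str, mode: str = "seed_2_8") -> str:
    """The sequence planted into positive sites: the reverse complement of
    miRNA nucleotides 2-8 (plus, in seed_plus_3prime mode, of nucleotides
    13-18 upstream of it, separated by a short spacer)."""
    seed_rc = reverse_complement(mirna_seq[1:8])
    if mode == "seed_2_8":
        return seed_rc
    three_prime_rc = reverse_complement(mirna_seq[12:18])
    return three_prime_rc + "AU" + seed_rc  # 3' block lies 5' of the seed match


def gen_positive_chimeras(
    mirnas: list[SequenceRecord], config: SynthConfig, rng: np.random.Generator
) -> list[Chimera]:
    """Label-1 chimeras: random-context sites containing the (possibly
    mutated) planted complement, total length 60-110 before padding."""
    out = []
    for _ in range(config.n_pos):
        mirna = mirnas[int(rng.integers(len(mirnas)))]
        total = int(rng.integers(config.min_chimera_length, CHIMERA_LENGTH + 1))
        match = _mutate(planted_match(mirna.seq, config.seed_match_mode),
                        config.mutation_rate, rng)
        site_len = max(total - len(mirna.seq), len(match))
        pos = int(rng.integers(0, min(site_len - len(match), config.max_site_offset) + 1))
        site = (
            _random_seq(pos, rng)
            + match
            + _random_seq(site_len - len(match) - pos, rng)
        )
        raw = concatenate_chimera(mirna, site)
        pad = generate_pad(
            mirna.seq, CHIMERA_LENGTH - len(raw), rng, mirna_id=mirna.id
        )
        out.append(
            Chimera(
                mirna_id=mirna.id,
                mirna_seq=mirna.seq,
                site_seq=site,
                pad_seq=pad,
                label=1,
            )
        )
    return out


def gen_dataset(
    config: SynthConfig | None = None,
    *,
    heldout_fraction: float = 0.0,
) -> tuple[DatasetTable, DatasetTable]:
    """Merged, shuffled positive + negative table (plus an optional
    held-out slice split off at ``heldout_fraction``).

    Negatives go through :func:`chimera_builder.sample_negative_sites`,
    the same pseudo-site procedure used for real transcript data.
    """
    if config is None:
        config = SynthConfig()
    rng = np.random.default_rng(config.seed)
    mirnas = gen_mirnas(config, rng)
    transcripts, regions = gen_transcripts(config, rng)
    positives = gen_positive_chimeras(mirnas, config, rng)
    negatives = sample_negative_sites(
        transcripts,
        regions,
        config.n_neg,
        mirnas,
        NegativeGenConfig(seed=config.seed),
        forbidden_pairs=set(),
        rng=rng,
    )
    merged = positives + negatives
    order = rng.permutation(len(merged))
    table = chimeras_to_table(
        (merged[i] for i in order), provenance=f"synthetic(seed={config.seed})"
    )
    n_held = int(round(heldout_fraction * len(table)))
    if n_held == 0:
        return table, DatasetTable([], [], provenance="heldout(empty)")
    main, held, _ = split_dataset(
        table, (len(table) - n_held, n_held, 0), rng
    )
    return main, held


def seed_match_baseline(
    table: DatasetTable, mirna_length: int = 21
) -> np.ndarray:
    """Trivial detector: predict 1 iff the site portion of each chimera
    contains the exact reverse complement of the prefix-miRNA's seed
    (nucleotides 2-8).  An upper-bound sanity check that the planted
    signal is present and learnable, not a model."""
    preds = np.zeros(len(table), dtype=np.int64)
    for i, seq in enumerate(table.sequences):
        mirna = seq[:mirna_length]
        preds[i] = int(reverse_complement(mirna[1:8]) in seq[mirna_length:])
    return preds
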