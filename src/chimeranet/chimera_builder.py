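"""Construction and encoding of 110-nt miRNA:target-site chimeras.

A *chimera* is the concatenation, 5'->3', of a mature miRNA sequence and a
candidate target-site sequence.  Positive (interacting) chimeras of fewer
than 110 nt are padded at the 3' end up to exactly 110 nt with random bases
that avoid any run of four or more contiguous bases able to pair with the
miRNA — so the pad cannot mimic a binding site.  Negative (pseudo) chimeras
are built with site length 110 - len(miRNA), hence carry no pad.

Each 110-nt chimera is one-hot encoded as a 110 x 4 matrix with fixed
column order A, U, G, C.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .exceptions import ChimeraTooLong, PadGenerationFailure, ValidationError
from .sequence_io import CHIMERA_LENGTH, DatasetTable, RegionInterval, SequenceRecord

BASES = "AUGC"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
#: Watson-Crick complement; G-U wobble handled separately where relevant.
_WC_PARTNER = {"A": "U", "U": "A", "G": "C", "C": "G"}

#: minimum contiguous pairing run forbidden between a pad and its miRNA
PAD_FORBIDDEN_RUN = 4
PAD_RETRY_CAP = 10_000

REGIONS = ("UTR3", "UTR5", "ORF")


@dataclass(frozen=True)
class Chimera:
    """A fully assembled 110-nt training/inference sequence with its label."""

    mirna_id: str
    mirna_seq: str
    site_seq: str
    pad_seq: str
    label: int
    region: str = "unknown"

    @property
    def full_seq(self) -> str:
        return self.mirna_seq + self.site_seq + self.pad_seq

    def __post_init__(self):
        if len(self.full_seq) != CHIMERA_LENGTH:
            raise ValidationError(
                f"chimera {self.mirna_id}: total length {len(self.full_seq)} "
                f"!= {CHIMERA_LENGTH}"
            )
        if self.label not in (0, 1):
            raise ValidationError(f"label {self.label!r} not in {{0, 1}}")


@dataclass
class EncodedBatch:
    """One-hot encoded chimeras: data (n, 110, 4) with binary labels (n,)."""

    data: np.ndarray
    labels: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.data.ndim != 3 or self.data.shape[1:] != (CHIMERA_LENGTH, 4):
            raise ValidationError(f"bad batch shape {self.data.shape}")
        if self.data.shape[0] != self.labels.shape[0]:
            raise ValidationError("data / labels length mismatch")

    def __len__(self) -> int:
        return self.data.shape[0]


@dataclass
class NegativeGenConfig:
    """How pseudo-negative chimeras are drawn from transcript regions.

    ``region_proportions`` is the UTR3:UTR5:ORF integer ratio (default
    7:2:1); counts are apportioned by largest remainder when the requested
    total is not divisible.
    """

    region_proportions: tuple[int, int, int] = (7, 2, 1)  # UTR3, UTR5, ORF
    chimera_length: int = CHIMERA_LENGTH
    seed: int = 0

    def __post_init__(self):
        if any(p <= 0 for p in self.region_proportions):
            raise ValidationError("region proportions must be positive")


# ---------------------------------------------------------------------------
# assembly


def concatenate_chimera(mirna: SequenceRecord, site: str) -> str:
    """Concatenate miRNA then target site, both 5'->3'.

    Raises :class:`ChimeraTooLong` if the result would exceed 110 nt,
    mirroring the removal of over-length chimeras during dataset curation.
    """
    if not site:
        raise ValidationError(f"{mirna.id}: empty target site")
    raw = mirna.seq + site
    if len(raw) > CHIMERA_LENGTH:
        raise ChimeraTooLong(
            f"{mirna.id}: miRNA ({len(mirna.seq)} nt) + site ({len(site)} nt) "
            f"= {len(raw)} nt > {CHIMERA_LENGTH}"
        )
    return raw


def _pairs(a: str, b: str, wobble: bool) -> bool:
    if _WC_PARTNER[a] == b:
        return True
    return wobble and {a, b} == {"G", "U"}


def _pad_is_safe(pad: str, mirna_seq: str, wobble: bool) -> bool:
    """True if no >=4-nt window of ``pad`` can pair contiguously
    (antiparallel) with any window of ``mirna_seq``."""
    k = PAD_FORBIDDEN_RUN
    if len(pad) < k or len(mirna_seq) < k:
        return True
    for i in range(len(pad) - k + 1):
        w = pad[i : i + k]
        for j in range(len(mirna_seq) - k + 1):
            m = mirna_seq[j : j + k]
            # antiparallel alignment: w[0] with m[k-1], ..., w[k-1] with m[0]
            if all(_pairs(w[t], m[k - 1 - t], wobble) for t in range(k)):
                return False
    return True


def generate_pad(
    mirna_seq: str,
    n: int,
    rng: np.random.Generator,
    *,
    wobble: bool = False,
    mirna_id: str = "?",
) -> str:
    """Random pad of length ``n`` avoiding 4 contiguous bases pairing with
    the miRNA.  Whole-pad rejection sampling; raises
    :class:`PadGenerationFailure` after :data:`PAD_RETRY_CAP` attempts.
    """
    if n < 0:
        raise ValidationError("pad length must be non-negative")
    if n == 0:
        return ""
    for _ in range(PAD_RETRY_CAP):
        pad = "".join(rng.choice(list(BASES), size=n))
        if _pad_is_safe(pad, mirna_seq, wobble):
            return pad
    raise PadGenerationFailure(
        f"could not generate a {n}-nt pad for miRNA {mirna_id} "
        f"within {PAD_RETRY_CAP} attempts"
    )


def pad_chimera(
    raw: str,
    mirna_seq: str,
    rng: np.random.Generator,
    *,
    wobble: bool = False,
) -> str:
    """Extend ``raw`` to exactly 110 nt; the original is kept as a prefix."""
    if len(raw) > CHIMERA_LENGTH:
        raise ChimeraTooLong(f"raw chimera of {len(raw)} nt > {CHIMERA_LENGTH}")
    return raw + generate_pad(mirna_seq, CHIMERA_LENGTH - len(raw), rng, wobble=wobble)


# ---------------------------------------------------------------------------
# encoding


def encode_one_hot(full_seq: str) -> np.ndarray:
    """One-hot encode a 110-nt chimera as a 110 x 4 matrix (columns A,U,G,C)."""
    if len(full_seq) != CHIMERA_LENGTH:
        raise ValidationError(f"sequence length {len(full_seq)} != {CHIMERA_LENGTH}")
    try:
        idx = np.fromiter((_BASE_INDEX[b] for b in full_seq), dtype=np.int64)
    except KeyError as exc:
        raise ValidationError(f"invalid base {exc.args[0]!r}") from exc
    mat = np.zeros((CHIMERA_LENGTH, 4), dtype=np.float32)
    mat[np.arange(CHIMERA_LENGTH), idx] = 1.0
    return mat


def decode_one_hot(mat: np.ndarray) -> str:
    mat = np.asarray(mat)
    if mat.shape != (CHIMERA_LENGTH, 4) or not np.all(mat.sum(axis=1) == 1):
        raise ValidationError("not a valid one-hot matrix")
    return "".join(BASES[i] for i in mat.argmax(axis=1))


def encode_batch(table: DatasetTable) -> EncodedBatch:
    data = np.stack([encode_one_hot(s) for s in table.sequences])
    return EncodedBatch(data, np.asarray(table.labels))


# ---------------------------------------------------------------------------
# pseudo-negative generation


def _apportion(n: int, proportions: Sequence[int]) -> list[int]:
    """Largest-remainder apportionment of ``n`` items to integer weights."""
    total = sum(proportions)
    quotas = [n * p / total for p in proportions]
    counts = [int(q) for q in quotas]
    remainder = n - sum(counts)
    order = sorted(range(len(quotas)), key=lambda i: quotas[i] - counts[i], reverse=True)
    for i in order[:remainder]:
        counts[i] += 1
    return counts


def sample_negative_sites(
    transcripts: Sequence[SequenceRecord],
    regions: Sequence[RegionInterval],
    n: int,
    mirnas: Sequence[SequenceRecord],
    config: NegativeGenConfig,
    forbidden_pairs: set[tuple[str, str]],
    rng: np.random.Generator,
) -> list[Chimera]:
    """Draw ``n`` pseudo-negative chimeras (label 0) from transcript regions.

    Site positions are sampled uniformly inside UTR3/UTR5/ORF intervals at
    the configured 7:2:1 ratio; each chimera is exactly 110 nt with an empty
    pad, and no (miRNA id, transcript id) combination in ``forbidden_pairs``
    is ever produced.
    """
    if n == 0:
        return []
    if not transcripts or not mirnas:
        raise ValidationError("need at least one transcript and one miRNA")
    seq_by_id = {t.id: t.seq for t in transcripts}
    by_region: dict[str, list[RegionInterval]] = {r: [] for r in REGIONS}
    for iv in regions:
        if iv.region in by_region and iv.transcript_id in seq_by_id:
            by_region[iv.region].append(iv)

    counts = dict(zip(REGIONS, _apportion(n, config.region_proportions)))
    out: list[Chimera] = []
    for region, want in counts.items():
        made = 0
        attempts = 0
        cap = max(10_000, 200 * max(want, 1))
        while made < want:
            attempts += 1
            if attempts > cap:
                raise ValidationError(
                    f"could not draw {want} pseudo-sites from region {region}: "
                    "no transcript region long enough or all pairs forbidden"
                )
            mirna = mirnas[rng.integers(len(mirnas))]
            site_len = config.chimera_length - len(mirna.seq)
            ivs = by_region[region]
            if not ivs:
                raise ValidationError(f"no annotated {region} intervals available")
            iv = ivs[rng.integers(len(ivs))]
            if (mirna.id, iv.transcript_id) in forbidden_pairs:
                continue
            if iv.end - iv.start < site_len:
                continue  # region too short for a full-length site
            start = int(rng.integers(iv.start, iv.end - site_len + 1))
            site = seq_by_id[iv.transcript_id][start : start + site_len]
            out.append(
                Chimera(
                    mirna_id=mirna.id,
                    mirna_seq=mirna.seq,
                    site_seq=site,
                    pad_seq="",
                    label=0,
                    region=region,
                )
            )
            made += 1
    return out


# ---------------------------------------------------------------------------
# dataset partitioning


def split_dataset(
    table: DatasetTable,
    sizes: tuple[int, int, int],
    rng: np.random.Generator,
) -> tuple[DatasetTable, DatasetTable, DatasetTable]:
    """Random disjoint train/validation/test partition with given sizes."""
    if sum(sizes) != len(table):
        raise ValidationError(f"sizes {sizes} do not sum to table size {len(table)}")
    perm = rng.permutation(len(table))
    bounds = np.cumsum([0, *sizes])
    names = ("train", "validation", "test")
    return tuple(
        table.subset(perm[bounds[i] : bounds[i + 1]].tolist(), provenance=names[i])
        for i in range(3)
    )


def kfold_split(
    table: DatasetTable,
    k: int,
    rng: np.random.Generator,
    *,
    stratify: bool = False,
) -> list[DatasetTable]:
    """Partition into k folds whose sizes differ by at most one.

    With ``stratify`` the class ratio is preserved per fold (used by the
    cross-validation driver so every fold contains both classes).
    """
    if k < 2:
        raise ValidationError("k must be >= 2")
    if k > len(table):
        raise ValidationError(f"k={k} exceeds table size {len(table)}")
    if stratify:
        labels = np.asarray(table.labels)
        fold_indices: list[list[int]] = [[] for _ in range(k)]
        cursor = 0
        for cls in (0, 1):
            cls_idx = np.flatnonzero(labels == cls)
            cls_idx = cls_idx[rng.permutation(len(cls_idx))]
            for i, idx in enumerate(cls_idx):
                fold_indices[(cursor + i) % k].append(int(idx))
            cursor += len(cls_idx)
        return [table.subset(ix, provenance=f"fold{j}") for j, ix in enumerate(fold_indices)]
    perm = rng.permutation(len(table))
    base, extra = divmod(len(table), k)
    folds, pos = [], 0
    for j in range(k):
        size = base + (1 if j < extra else 0)
        folds.append(table.subset(perm[pos : pos + size].tolist(), provenance=f"fold{j}"))
        pos += size
    return folds


def chimeras_to_table(chimeras: Iterable[Chimera], provenance: str = "") -> DatasetTable:
    chims = list(chimeras)
    return DatasetTable(
        [c.full_seq for c in chims], [c.label for c in chims], provenance
    )
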