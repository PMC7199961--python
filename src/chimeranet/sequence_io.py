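"""Sequence and dataset-table input/output.

Sequences are handled as RNA over the four-letter alphabet {A, U, G, C}.
DNA input (T instead of U) is accepted and mapped to RNA on read; any other
symbol is rejected rather than silently encoded, because the downstream
one-hot representation defines exactly four channels.

Dataset tables hold fixed-length (110 nt) miRNA:target-site chimera
sequences with binary labels.  The canonical on-disk format is TSV with
columns ``chimera_seq`` and ``label``; XLSX files with the same columns are
readable for compatibility with supplementary-style spreadsheets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .exceptions import AlphabetError, FastaParseError, ValidationError

RNA_ALPHABET = frozenset("AUGC")

#: Fixed total chimera length (miRNA + target site + pad), in nucleotides.
CHIMERA_LENGTH = 110


@dataclass(frozen=True)
class SequenceRecord:
    """An identified RNA sequence."""

    id: str
    seq: str

    def __post_init__(self):
        if not self.seq:
            raise ValidationError(f"record {self.id!r}: empty sequence")
        _check_alphabet(self.seq, context=self.id)

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class DatasetTable:
    """Rows of (110-nt chimera sequence, binary label)."""

    sequences: list[str]
    labels: list[int]
    provenance: str = ""

    def __post_init__(self):
        if len(self.sequences) != len(self.labels):
            raise ValidationError(
                f"{len(self.sequences)} sequences but {len(self.labels)} labels"
            )
        for i, (seq, lab) in enumerate(zip(self.sequences, self.labels)):
            if len(seq) != CHIMERA_LENGTH:
                raise ValidationError(
                    f"row {i}: sequence length {len(seq)} != {CHIMERA_LENGTH}"
                )
            _check_alphabet(seq, context=f"row {i}")
            if lab not in (0, 1):
                raise ValidationError(f"row {i}: label {lab!r} not in {{0, 1}}")

    def __len__(self) -> int:
        return len(self.sequences)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, DatasetTable)
            and self.sequences == other.sequences
            and self.labels == other.labels
        )

    def subset(self, indices: Sequence[int], provenance: str = "") -> "DatasetTable":
        return DatasetTable(
            [self.sequences[i] for i in indices],
            [self.labels[i] for i in indices],
            provenance or self.provenance,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"chimera_seq": self.sequences, "label": self.labels})


def _check_alphabet(seq: str, context: str = "") -> None:
    if not set(seq) - RNA_ALPHABET:  # fast path for valid sequences
        return
    for pos, ch in enumerate(seq, start=1):
        if ch not in RNA_ALPHABET:
            raise AlphabetError(ch, pos, context)


def normalize_sequence(raw: str) -> str:
    """Uppercase, map DNA T to RNA U, and validate the alphabet.

    Raises :class:`AlphabetError` naming the first offending symbol and its
    1-based position.
    """
    if not raw:
        raise ValidationError("empty sequence")
    seq = raw.upper().replace("T", "U")
    _check_alphabet(seq)
    return seq


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into normalized :class:`SequenceRecord` objects.

    Record ids are the first whitespace-delimited token of the header.
    Multi-line sequences are concatenated.  An empty file yields an empty
    list.  Sequence data appearing before any header is a parse error.
    """
    path = Path(path)
    # pre-scan for data before the first header, which SeqIO silently skips
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise FastaParseError("sequence data before first '>' header", lineno)
            break
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(SequenceRecord(id=rec.id, seq=normalize_sequence(str(rec.seq))))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    bio = [
        BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in records
    ]
    SeqIO.write(bio, str(Path(path)), "fasta")


def read_dataset_table(path: str | Path) -> DatasetTable:
    """Read a chimera dataset from TSV (canonical) or XLSX.

    The file must have ``chimera_seq`` and ``label`` columns; every sequence
    must be exactly 110 nt and every label 0 or 1 (validation errors name
    the offending row).
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        frame = pd.read_excel(path)
    else:
        frame = pd.read_csv(path, sep="\t")
    missing = {"chimera_seq", "label"} - set(frame.columns)
    if missing:
        raise ValidationError(f"{path}: missing column(s) {sorted(missing)}")
    seqs = [normalize_sequence(s) for s in frame["chimera_seq"].astype(str)]
    labels = [int(x) for x in frame["label"]]
    return DatasetTable(seqs, labels, provenance=str(path))


def write_dataset_table(table: DatasetTable, path: str | Path) -> None:
    table.to_frame().to_csv(Path(path), sep="\t", index=False)


@dataclass(frozen=True)
class RegionInterval:
    """A transcript region annotation: 0-based half-open interval."""

    transcript_id: str
    start: int
    end: int
    region: str  # UTR5 | ORF | UTR3

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise ValidationError(
                f"{self.transcript_id}: bad interval [{self.start}, {self.end})"
            )


def read_region_table(path: str | Path) -> list[RegionInterval]:
    """Read a BED-like region sidecar (transcript_id, start, end, region)."""
    frame = pd.read_csv(
        Path(path), sep="\t", header=None,
        names=["transcript_id", "start", "end", "region"],
    )
    return [
        RegionInterval(str(r.transcript_id), int(r.start), int(r.end), str(r.region))
        for r in frame.itertuples()
    ]


def write_region_table(regions: Iterable[RegionInterval], path: str | Path) -> None:
    with open(Path(path), "w") as fh:
        for r in regions:
            fh.write(f"{r.transcript_id}\t{r.start}\t{r.end}\t{r.region}\n")
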