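"""Sequence and alignment-table data model shared by every pipeline stage.

Coordinates are 0-based half-open on the forward strand of the read
everywhere inside the package; the tabular alignment dialect (1-based
inclusive, possibly reversed) is converted on ingestion and never leaks
past this module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

__all__ = [
    "SequenceRecord",
    "AlignmentHit",
    "reverse_complement",
    "normalize_sequence",
    "read_fasta",
    "write_fasta",
    "read_alignment_table",
    "write_alignment_table",
    "ALIGNMENT_COLUMNS",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID = frozenset("ACGTN")
# IUPAC ambiguity codes seen in Sanger reads; mapped to N by default.
_AMBIGUOUS = frozenset("RYSWKMBDHVU")


@dataclass
class SequenceRecord:
    """A nucleotide sequence (read or promoter) with provenance.

    ``strand`` and ``offset`` locate the sequence on its ``source_read``:
    ``offset`` is the 0-based start of the region on the read's forward
    strand, and ``strand`` says whether ``sequence`` is that region as-is
    (``+``) or its reverse complement (``-``).
    """

    id: str
    sequence: str
    description: str = ""
    source_read: str | None = None
    strand: str = "+"
    offset: int = 0

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        bad = set(self.sequence) - _VALID
        if bad:
            raise ValueError(
                f"record {self.id!r}: invalid characters {sorted(bad)}; "
                "normalize_sequence() before constructing"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class AlignmentHit:
    """One protein-alignment row tying a read interval to a protein subject.

    ``read_start``/``read_end`` are normalized 0-based half-open forward
    strand coordinates; the original query orientation is kept in
    ``frame_sign``.
    """

    read_id: str
    subject_id: str
    percent_identity: float
    alignment_length_aa: int
    read_start: int
    read_end: int
    frame_sign: str
    bitscore: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError(f"percent identity {self.percent_identity} outside [0, 100]")
        if self.alignment_length_aa < 1:
            raise ValueError("alignment length must be >= 1 amino acid")
        if self.read_start >= self.read_end:
            raise ValueError(
                f"hit on {self.read_id!r}: start {self.read_start} >= end {self.read_end}"
            )
        if self.frame_sign not in ("+", "-"):
            raise ValueError(f"frame_sign must be '+' or '-', got {self.frame_sign!r}")


def normalize_sequence(seq: str, *, record_id: str = "?", ambiguous: str = "map_to_n") -> tuple[str, int]:
    """Uppercase ``seq`` and resolve non-ACGTN characters.

    ``ambiguous='map_to_n'`` maps IUPAC ambiguity codes to ``N`` and returns
    how many were mapped; ``ambiguous='error'`` rejects them. Characters that
    are not nucleotides at all are always an error.
    """
    if ambiguous not in ("map_to_n", "error"):
        raise ValueError(f"unknown ambiguity policy {ambiguous!r}")
    up = seq.upper()
    chars = set(up)
    bad = chars - _VALID - _AMBIGUOUS
    if bad:
        raise ValueError(f"record {record_id!r}: non-nucleotide characters {sorted(bad)}")
    amb = chars & _AMBIGUOUS
    if not amb:
        return up, 0
    if ambiguous == "error":
        raise ValueError(f"record {record_id!r}: ambiguity codes {sorted(amb)} present")
    n_mapped = sum(up.count(c) for c in amb)
    return up.translate(str.maketrans({c: "N" for c in amb})), n_mapped


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement over the A/C/G/T/N alphabet."""
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(f"invalid characters for reverse complement: {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


def read_fasta(path: str | Path, *, ambiguous: str = "map_to_n") -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects, order preserved.

    Sequences are uppercased; IUPAC ambiguity codes are mapped to ``N`` with
    a counted warning (or rejected with ``ambiguous='error'``). Duplicate ids
    are an error; an empty file yields an empty list with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    mapped = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq, n = normalize_sequence(str(rec.seq), record_id=rec.id, ambiguous=ambiguous)
        mapped += n
        desc = rec.description[len(rec.id):].strip() if rec.description.startswith(rec.id) else rec.description
        records.append(SequenceRecord(id=rec.id, sequence=seq, description=desc))
    if mapped:
        warnings.warn(f"{path}: mapped {mapped} ambiguity bases to N", stacklevel=2)
    if not records:
        warnings.warn(f"{path}: no FASTA records found", stacklevel=2)
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, *, width: int = 70) -> None:
    """Write records as FASTA, wrapping sequence lines at ``width`` columns."""
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            header = f">{rec.id} {rec.description}".rstrip()
            fh.write(header + "\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


ALIGNMENT_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_alignment_table(path: str | Path) -> list[AlignmentHit]:
    """Parse a 12-column tabular protein-alignment file (BLAST outfmt-6 dialect).

    ``qstart``/``qend`` are 1-based inclusive nucleotide coordinates on the
    read; a reversed pair (start > end) marks a minus-frame hit. Both are
    normalized to 0-based half-open forward-strand intervals.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=ALIGNMENT_COLUMNS,
                         comment="#", dtype={"qseqid": str, "sseqid": str})
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path}: empty alignment table", stacklevel=2)
        return []
    hits: list[AlignmentHit] = []
    for idx, row in enumerate(df.itertuples(index=False), start=1):
        try:
            qstart, qend = int(row.qstart), int(row.qend)
            if qstart == qend:
                raise ValueError("qstart == qend")
            frame_sign = "+" if qstart < qend else "-"
            lo, hi = min(qstart, qend), max(qstart, qend)
            hits.append(
                AlignmentHit(
                    read_id=str(row.qseqid),
                    subject_id=str(row.sseqid),
                    percent_identity=float(row.pident),
                    alignment_length_aa=int(row.length),
                    read_start=lo - 1,
                    read_end=hi,
                    frame_sign=frame_sign,
                    bitscore=float(row.bitscore),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}, line {idx}: malformed alignment row ({exc})") from exc
    return hits


def write_alignment_table(hits: Iterable[AlignmentHit], path: str | Path) -> None:
    """Write hits back to the 12-column tabular dialect (1-based inclusive
    query coordinates, reversed pair for minus-frame hits)."""
    with Path(path).open("w") as fh:
        for h in hits:
            qstart, qend = h.read_start + 1, h.read_end
            if h.frame_sign == "-":
                qstart, qend = qend, qstart
            fh.write(
                "\t".join(map(str, [
                    h.read_id, h.subject_id, h.percent_identity, h.alignment_length_aa,
                    0, 0, qstart, qend, 1, h.alignment_length_aa, "1e-50", h.bitscore,
                ])) + "\n"
            )
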