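"""Promoter identification from long metagenomic reads.

The protocol keeps reads long enough to host both a detectable coding
region and a fixed-length upstream segment, requires a strong protein hit
(>= 150 aligned amino acids, > 50% identity), demands at least 300 nt of
non-coding sequence upstream of the hit, extracts exactly 300 nt adjacent
to the coding start (gene-strand oriented), collapses near-duplicates at
98% global-alignment identity, and finally removes externally flagged
reads/regions (eukaryotic, ncRNA, CRISPR — produced by external tools and
consumed here as id lists).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import edlib

from .seqio import AlignmentHit, SequenceRecord, reverse_complement

__all__ = [
    "PromoterRecord",
    "ExtractionReport",
    "filter_reads_by_length",
    "select_coding_hits",
    "extract_upstream",
    "alignment_identity",
    "deduplicate_promoters",
    "apply_exclusions",
    "extract_promoters",
]


@dataclass
class PromoterRecord(SequenceRecord):
    """A fixed-length putative promoter, 5'->3' on the strand of its gene.

    The last base of ``sequence`` is immediately adjacent to the coding
    start of the downstream gene (``gene_subject``).
    """

    gene_subject: str = ""
    environment: str = ""
    function_label: str | None = None


@dataclass
class ExtractionReport:
    """Stage-by-stage survivor counts; monotone non-increasing after input."""

    n_input_reads: int = 0
    n_length_pass: int = 0
    n_with_hit: int = 0
    n_with_upstream: int = 0
    n_promoters: int = 0
    n_after_dedup: int = 0
    n_after_exclusions: int = 0
    rejection_reasons: dict = field(default_factory=dict)

    def as_rows(self) -> list[tuple[str, int]]:
        return [
            ("input_reads", self.n_input_reads),
            ("length_pass", self.n_length_pass),
            ("with_accepted_hit", self.n_with_hit),
            ("with_sufficient_upstream", self.n_with_upstream),
            ("promoters_extracted", self.n_promoters),
            ("after_deduplication", self.n_after_dedup),
            ("after_exclusions", self.n_after_exclusions),
        ]


def filter_reads_by_length(reads: Sequence[SequenceRecord], min_length: int = 800) -> list[SequenceRecord]:
    """Keep reads of length >= ``min_length`` (default 800 nt), order preserved."""
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    return [r for r in reads if len(r) >= min_length]


def select_coding_hits(
    hits: Iterable[AlignmentHit],
    min_alignment_aa: int = 150,
    min_identity: float = 50.0,
) -> dict[str, AlignmentHit]:
    """Select the single best accepted protein hit per read.

    A hit is accepted when it spans at least ``min_alignment_aa`` aligned
    amino acids and has identity strictly greater than ``min_identity``
    percent. Among a read's accepted hits the winner is the highest
    bitscore, ties broken by lowest read_start, then subject id.
    """
    passing = [
        h for h in hits
        if h.alignment_length_aa >= min_alignment_aa and h.percent_identity > min_identity
    ]
    best: dict[str, AlignmentHit] = {}
    for h in passing:
        cur = best.get(h.read_id)
        if cur is None or (-h.bitscore, h.read_start, h.subject_id) < (-cur.bitscore, cur.read_start, cur.subject_id):
            best[h.read_id] = h
    return best


def extract_upstream(
    read: SequenceRecord,
    hit: AlignmentHit,
    upstream_length: int = 300,
    require_noncoding: int = 300,
    other_hits: Sequence[AlignmentHit] = (),
) -> tuple[PromoterRecord | None, str]:
    """Extract the promoter upstream of ``hit`` or reject the read.

    For a plus-frame hit the candidate window is the ``require_noncoding``
    bases ending at the hit start on the forward strand; for a minus-frame
    hit it is the bases starting at the hit end, reverse-complemented so the
    emitted promoter always reads 5'->3' into the gene. Rejection reasons:
    ``insufficient_upstream`` (window leaves the read) and
    ``overlaps_other_hit`` (window intersects another accepted coding hit).

    Returns ``(record, "ok")`` or ``(None, reason)``.
    """
    if hit.read_id != read.id:
        raise ValueError(f"hit read {hit.read_id!r} does not match read {read.id!r}")
    if hit.read_end > len(read):
        raise ValueError(f"hit {hit.read_id!r} coordinates [{hit.read_start},{hit.read_end}) exceed read length {len(read)}")

    if hit.frame_sign == "+":
        win_start, win_end = hit.read_start - require_noncoding, hit.read_start
        if win_start < 0:
            return None, "insufficient_upstream"
        prom_start, prom_end = hit.read_start - upstream_length, hit.read_start
        strand = "+"
    else:
        win_start, win_end = hit.read_end, hit.read_end + require_noncoding
        if win_end > len(read):
            return None, "insufficient_upstream"
        prom_start, prom_end = hit.read_end, hit.read_end + upstream_length
        strand = "-"

    for other in other_hits:
        if other is hit or other.read_id != read.id:
            continue
        if other.read_start < win_end and win_start < other.read_end:
            return None, "overlaps_other_hit"

    raw = read.sequence[prom_start:prom_end]
    seq = reverse_complement(raw) if strand == "-" else raw
    rec = PromoterRecord(
        id=f"{read.id}|{strand}|{prom_start}",
        sequence=seq,
        description=f"upstream of {hit.subject_id}",
        source_read=read.id,
        strand=strand,
        offset=prom_start,
        gene_subject=hit.subject_id,
    )
    return rec, "ok"


def alignment_identity(a: str, b: str) -> float:
    """Global-alignment identity: matches / alignment columns.

    Equal-length sequences (the only case the fixed-length promoter
    pipeline produces) are compared column-wise without gaps, so k
    substitutions over length L give exactly (L-k)/L. Unequal lengths fall
    back to a minimum-edit-distance global alignment with every indel
    position counted as one column.
    """
    if a == b:
        return 1.0
    if len(a) == len(b):
        matches = sum(x == y for x, y in zip(a, b))
        return matches / len(a)
    res = edlib.align(a, b, mode="NW", task="path")
    matches = columns = 0
    for length, op in re.findall(r"(\d+)([=XID])", res["cigar"]):
        n = int(length)
        columns += n
        if op == "=":
            matches += n
    return matches / columns


def deduplicate_promoters(
    promoters: Sequence[PromoterRecord],
    identity_cutoff: float = 0.98,
) -> tuple[list[PromoterRecord], dict[str, str]]:
    """Greedy redundancy removal at ``identity_cutoff`` (default 98%).

    Promoters are visited in a deterministic order (descending count of
    non-N bases, then id); each joins the first existing representative it
    matches at or above the cutoff, otherwise founds a new cluster. Returns
    the representatives (in founding order) and a member -> representative
    id map covering every input promoter.
    """
    if not 0 < identity_cutoff <= 1:
        raise ValueError("identity_cutoff must be in (0, 1]")
    ordered = sorted(promoters, key=lambda p: (-(len(p.sequence) - p.sequence.count("N")), p.id))
    reps: list[PromoterRecord] = []
    assignment: dict[str, str] = {}
    for prom in ordered:
        for rep in reps:
            if alignment_identity(prom.sequence, rep.sequence) >= identity_cutoff:
                assignment[prom.id] = rep.id
                break
        else:
            reps.append(prom)
            assignment[prom.id] = prom.id
    return reps, assignment


def apply_exclusions(
    promoters: Sequence[PromoterRecord],
    excluded_read_ids: Iterable[str] = (),
    excluded_promoter_ids: Iterable[str] = (),
) -> tuple[list[PromoterRecord], dict[str, int]]:
    """Drop promoters flagged by external exclusion lists.

    A promoter is removed when its own id or its source read's id is listed
    (eukaryotic reads, ncRNA/secondary coding regions, CRISPR arrays — all
    identified by external tools). Unknown ids warn but do not fail.
    """
    read_ids = set(excluded_read_ids)
    prom_ids = set(excluded_promoter_ids)
    kept: list[PromoterRecord] = []
    removed_by_read = removed_by_prom = 0
    for p in promoters:
        if p.source_read in read_ids:
            removed_by_read += 1
        elif p.id in prom_ids:
            removed_by_prom += 1
        else:
            kept.append(p)
    known_reads = {p.source_read for p in promoters}
    known_proms = {p.id for p in promoters}
    unknown = (read_ids - known_reads) | (prom_ids - known_proms)
    if unknown:
        warnings.warn(f"{len(unknown)} exclusion ids not present in promoter set", stacklevel=2)
    return kept, {"excluded_by_read": removed_by_read, "excluded_by_promoter": removed_by_prom}


def extract_promoters(
    reads: Sequence[SequenceRecord],
    hits: Sequence[AlignmentHit],
    *,
    min_read_length: int = 800,
    min_alignment_aa: int = 150,
    min_identity: float = 50.0,
    upstream_length: int = 300,
    require_noncoding: int = 300,
    dedup_identity: float = 0.98,
    excluded_read_ids: Iterable[str] = (),
    excluded_promoter_ids: Iterable[str] = (),
    environment: str = "",
) -> tuple[list[PromoterRecord], ExtractionReport, dict[str, str]]:
    """Run the full promoter-identification pipeline on one sample.

    Returns the surviving promoters, a stage-count report, and the
    de-redundancy cluster map (member id -> representative id).
    """
    report = ExtractionReport(n_input_reads=len(reads))
    long_reads = filter_reads_by_length(reads, min_read_length)
    report.n_length_pass = len(long_reads)
    long_ids = {r.id for r in long_reads}

    best = select_coding_hits(
        [h for h in hits if h.read_id in long_ids], min_alignment_aa, min_identity
    )
    report.n_with_hit = len(best)
    # All of a read's accepted best hits can invalidate another read's window
    # only on the same read; collect per-read passing hits for the overlap test.
    passing_by_read: dict[str, list[AlignmentHit]] = {}
    for h in hits:
        if h.read_id in long_ids and h.alignment_length_aa >= min_alignment_aa and h.percent_identity > min_identity:
            passing_by_read.setdefault(h.read_id, []).append(h)

    promoters: list[PromoterRecord] = []
    reasons: dict[str, int] = {}
    n_with_upstream = 0
    for read in long_reads:
        hit = best.get(read.id)
        if hit is None:
            continue
        rec, reason = extract_upstream(
            read, hit, upstream_length, require_noncoding,
            other_hits=passing_by_read.get(read.id, ()),
        )
        if reason != "insufficient_upstream":
            n_with_upstream += 1
        if rec is None:
            reasons[reason] = reasons.get(reason, 0) + 1
            continue
        rec.environment = environment
        promoters.append(rec)
    report.n_with_upstream = n_with_upstream
    report.n_promoters = len(promoters)
    report.rejection_reasons = reasons

    reps, assignment = deduplicate_promoters(promoters, dedup_identity)
    report.n_after_dedup = len(reps)

    kept, _counts = apply_exclusions(reps, excluded_read_ids, excluded_promoter_ids)
    report.n_after_exclusions = len(kept)
    return kept, report, assignment
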