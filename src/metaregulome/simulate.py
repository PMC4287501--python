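"""Deterministic synthetic-data generators with machine-readable ground truth.

These generators emulate the pipeline's inputs — long reads with mock
protein-alignment tables, promoter sets with planted palindromic dimers,
and function annotations — such that every expected intermediate count of
the pipeline is computable from the recorded truth without running the
pipeline. All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .dimers import PalindromicDimer
from .promoters import PromoterRecord
from .regstats import FunctionAnnotation
from .seqio import AlignmentHit, SequenceRecord, reverse_complement

__all__ = [
    "PlantTruth",
    "ReadFixture",
    "generate_background_promoters",
    "plant_dimer",
    "generate_read_fixture",
    "generate_annotations",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_sequence(rng: np.random.Generator, length: int, gc_fraction: float = 0.5) -> str:
    p = np.array([(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2])
    return rng.choice(_BASES, size=length, p=p).tobytes().decode("ascii")


def generate_background_promoters(
    n: int, length: int = 300, gc_fraction: float = 0.5, seed: int = 0,
    environment: str = "synthetic", id_prefix: str = "synthP",
) -> list[PromoterRecord]:
    """I.i.d. background promoters with P(G)=P(C)=gc/2, P(A)=P(T)=(1-gc)/2."""
    if n < 1 or length < 1:
        raise ValueError("n and length must be >= 1")
    if not 0 <= gc_fraction <= 1:
        raise ValueError("gc_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    return [
        PromoterRecord(
            id=f"{id_prefix}{i:05d}", sequence=_random_sequence(rng, length, gc_fraction),
            environment=environment,
        )
        for i in range(n)
    ]


@dataclass
class PlantTruth:
    """Ground truth for planted dimer instances."""

    dimer_name: str
    positions: dict[str, list[tuple[int, int]]]  # promoter id -> [(start, end)]
    fraction: float
    copies_per_promoter: int
    seed: int

    @property
    def planted_ids(self) -> set[str]:
        return set(self.positions)

    @property
    def n_sites(self) -> int:
        return sum(len(v) for v in self.positions.values())


def plant_dimer(
    promoters: Sequence[PromoterRecord],
    dimer: PalindromicDimer,
    fraction: float,
    copies_per_promoter: int = 1,
    seed: int = 0,
    max_retries: int = 200,
) -> tuple[list[PromoterRecord], PlantTruth]:
    """Overwrite dimer instances into a random subset of promoters.

    ``round(fraction * n)`` promoters, chosen uniformly, each receive
    ``copies_per_promoter`` non-overlapping instances at uniform positions.
    Spacer bases are drawn at random per instance, so discovery must rely
    on the palindromic flanks — the spacer carries no signal.
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_plant = round(fraction * len(promoters))
    chosen = set(rng.choice(len(promoters), size=n_plant, replace=False)) if n_plant else set()
    L = dimer.length
    out: list[PromoterRecord] = []
    positions: dict[str, list[tuple[int, int]]] = {}
    for i, p in enumerate(promoters):
        if i not in chosen:
            out.append(p)
            continue
        if len(p.sequence) < L:
            raise ValueError(f"promoter {p.id!r} shorter than motif length {L}")
        placed: list[tuple[int, int]] = []
        for _ in range(copies_per_promoter):
            for _try in range(max_retries):
                start = int(rng.integers(0, len(p.sequence) - L + 1))
                if all(start + L <= s or e <= start for s, e in placed):
                    placed.append((start, start + L))
                    break
            else:
                raise ValueError(f"cannot place {copies_per_promoter} non-overlapping "
                                 f"instances in promoter {p.id!r}")
        seq = list(p.sequence)
        for start, end in placed:
            spacer = _random_sequence(rng, dimer.spacer) if dimer.spacer else ""
            seq[start:end] = dimer.w1 + spacer + dimer.w2
        out.append(PromoterRecord(
            id=p.id, sequence="".join(seq), description=p.description,
            source_read=p.source_read, strand=p.strand, offset=p.offset,
            gene_subject=p.gene_subject, environment=p.environment,
        ))
        positions[p.id] = sorted(placed)
    truth = PlantTruth(dimer_name=dimer.name, positions=positions, fraction=fraction,
                       copies_per_promoter=copies_per_promoter, seed=seed)
    return out, truth


@dataclass
class ReadFixture:
    """Reads + mock alignment table + per-read expected pipeline outcome.

    ``truth[read_id]`` records which extraction filters the read passes and,
    where applicable, the expected promoter interval/strand/sequence.
    ``expected_*`` aggregate the per-read truth into the exact
    stage-by-stage counts the extraction report must reproduce.
    """

    reads: list[SequenceRecord]
    hits: list[AlignmentHit]
    truth: dict[str, dict]
    upstream_length: int
    expected_promoter_ids: list[str] = field(default_factory=list)
    expected_rep_ids: list[str] = field(default_factory=list)
    expected_counts: dict[str, int] = field(default_factory=dict)

    def expected_promoter_sequence(self, read_id: str) -> str:
        t = self.truth[read_id]
        read = next(r for r in self.reads if r.id == read_id)
        start, end, strand = t["promoter"]
        seg = read.sequence[start:end]
        return reverse_complement(seg) if strand == "-" else seg


def _mutate(seq: str, positions: Sequence[int], rng: np.random.Generator) -> str:
    chars = list(seq)
    for pos in positions:
        alternatives = [b for b in "ACGT" if b != chars[pos]]
        chars[pos] = alternatives[int(rng.integers(0, 3))]
    return "".join(chars)


def generate_read_fixture(
    seed: int = 0,
    n_replicates: int = 1,
    upstream_length: int = 300,
    min_read_length: int = 800,
) -> ReadFixture:
    """Boundary-case reads with a consistent mock alignment table.

    The class layout exercises every extraction filter at its edge: read
    lengths 799/800, alignment lengths 149/150 aa, identities 50.0/50.1%,
    a minus-frame hit, a read with only 250 nt upstream, an operon-like
    read whose upstream window overlaps a second coding hit, a
    bitscore tie-break pair, and a near-duplicate promoter trio (5 and 10
    mismatches over 300 nt) for the 98% de-redundancy step.
    """
    rng = np.random.default_rng(seed)
    reads: list[SequenceRecord] = []
    hits: list[AlignmentHit] = []
    truth: dict[str, dict] = {}

    def add_read(rid: str, seq: str, read_hits: list[tuple], expected: dict) -> None:
        reads.append(SequenceRecord(id=rid, sequence=seq))
        for (start, end, pident, aa, sign, bits, subj) in read_hits:
            hits.append(AlignmentHit(read_id=rid, subject_id=subj, percent_identity=pident,
                                     alignment_length_aa=aa, read_start=start, read_end=end,
                                     frame_sign=sign, bitscore=bits))
        truth[rid] = expected

    for rep in range(n_replicates):
        s = f"_{rep}"
        add_read(f"short799{s}", _random_sequence(rng, 799),
                 [(349, 799, 99.0, 150, "+", 300.0, "prot_short")],
                 {"passes_length": False, "accepted_hit": False, "upstream_ok": False, "promoter": None})
        seq = _random_sequence(rng, 800)
        add_read(f"len800pass{s}", seq,
                 [(350, 800, 99.0, 150, "+", 300.0, "prot_len800")],
                 {"passes_length": True, "accepted_hit": True, "upstream_ok": True,
                  "promoter": (350 - upstream_length, 350, "+")})
        add_read(f"ident50_0{s}", _random_sequence(rng, 1000),
                 [(400, 850, 50.0, 150, "+", 300.0, "prot_i500")],
                 {"passes_length": True, "accepted_hit": False, "upstream_ok": False, "promoter": None})
        add_read(f"ident50_1{s}", _random_sequence(rng, 1000),
                 [(400, 850, 50.1, 150, "+", 300.0, "prot_i501")],
                 {"passes_length": True, "accepted_hit": True, "upstream_ok": True,
                  "promoter": (100, 400, "+")})
        add_read(f"aa149{s}", _random_sequence(rng, 1000),
                 [(400, 847, 90.0, 149, "+", 300.0, "prot_aa149")],
                 {"passes_length": True, "accepted_hit": False, "upstream_ok": False, "promoter": None})
        add_read(f"minuspass{s}", _random_sequence(rng, 1000),
                 [(100, 550, 90.0, 150, "-", 300.0, "prot_minus")],
                 {"passes_length": True, "accepted_hit": True, "upstream_ok": True,
                  "promoter": (550, 550 + upstream_length, "-")})
        add_read(f"upstream250{s}", _random_sequence(rng, 1000),
                 [(250, 700, 90.0, 150, "+", 300.0, "prot_up250")],
                 {"passes_length": True, "accepted_hit": True, "upstream_ok": False, "promoter": None})
        add_read(f"operon{s}", _random_sequence(rng, 1200),
                 [(700, 1150, 90.0, 150, "+", 300.0, "prot_opA"),
                  (100, 550, 90.0, 150, "+", 200.0, "prot_opB")],
                 {"passes_length": True, "accepted_hit": True, "upstream_ok": True,
                  "promoter": None, "rejected": "overlaps_other_hit"})
        add_read(f"nohit{s}", _random_sequence(rng, 1000), [],
                 {"passes_length": True, "accepted_hit": False, "upstream_ok": False, "promoter": None})
        add_read(f"twohits{s}", _random_sequence(rng, 1000),
                 [(400, 850, 90.0, 150, "+", 210.0, "prot_best"),
                  (430, 880, 90.0, 150, "+", 180.0, "prot_second")],
                 {"passes_length": True, "accepted_hit": True, "upstream_ok": True,
                  "promoter": (100, 400, "+"), "best_subject": "prot_best"})

    # near-duplicate trio for the de-redundancy boundary (5 vs 10 mismatches
    # over a 300-nt promoter: 98.3% clusters, 96.7% does not)
    base = _random_sequence(rng, 800)
    prom_window = (350 - upstream_length, 350)
    dup_expected = {"passes_length": True, "accepted_hit": True, "upstream_ok": True,
                    "promoter": (prom_window[0], prom_window[1], "+")}
    add_read("dup_a", base, [(350, 800, 99.0, 150, "+", 300.0, "prot_dupA")], dict(dup_expected))
    pos5 = sorted(rng.choice(np.arange(prom_window[0], prom_window[1]), size=5, replace=False).tolist())
    add_read("dup_b5", _mutate(base, pos5, rng),
             [(350, 800, 99.0, 150, "+", 300.0, "prot_dupB5")],
             {**dup_expected, "dedup_into": "dup_a"})
    pos10 = sorted(rng.choice(np.arange(prom_window[0], prom_window[1]), size=10, replace=False).tolist())
    add_read("dup_b10", _mutate(base, pos10, rng),
             [(350, 800, 99.0, 150, "+", 300.0, "prot_dupB10")], dict(dup_expected))

    promoter_ids = [
        f"{rid}|{t['promoter'][2]}|{t['promoter'][0]}"
        for rid, t in truth.items() if t["promoter"] is not None
    ]
    rep_ids = [
        f"{rid}|{t['promoter'][2]}|{t['promoter'][0]}"
        for rid, t in truth.items()
        if t["promoter"] is not None and "dedup_into" not in t
    ]
    expected_counts = {
        "input_reads": len(reads),
        "length_pass": sum(t["passes_length"] for t in truth.values()),
        "with_accepted_hit": sum(t["accepted_hit"] for t in truth.values()),
        "with_sufficient_upstream": sum(t["upstream_ok"] for t in truth.values()),
        "promoters_extracted": len(promoter_ids),
        "after_deduplication": len(rep_ids),
        "after_exclusions": len(rep_ids),
    }
    return ReadFixture(reads=reads, hits=hits, truth=truth, upstream_length=upstream_length,
                       expected_promoter_ids=sorted(promoter_ids),
                       expected_rep_ids=sorted(rep_ids),
                       expected_counts=expected_counts)


def generate_annotations(
    promoters: Sequence[PromoterRecord],
    seed: int = 0,
    planted_ids: set[str] | frozenset[str] = frozenset(),
    enriched_label: str = "Stress Response;SOS response",
    background_labels: Sequence[str] = (
        "Carbohydrates;Central carbohydrate metabolism",
        "Carbohydrates;Monosaccharides",
        "Protein Metabolism;Protein biosynthesis",
        "Membrane Transport;ABC transporters",
        "RNA Metabolism;Transcription",
    ),
    mode: str = "planted",
) -> list[FunctionAnnotation]:
    """Assign one hierarchical SEED-style label path per promoter.

    ``planted`` mode gives every promoter in ``planted_ids`` the enriched
    label and everyone else a uniform background label, constructing a known
    enrichment outcome; ``uniform`` mode draws uniformly from the union (the
    calibration case, no signal).
    """
    rng = np.random.default_rng(seed)
    all_labels = list(background_labels) + [enriched_label]
    out: list[FunctionAnnotation] = []
    for p in promoters:
        if mode == "planted":
            if p.id in planted_ids:
                label = enriched_label
            else:
                label = background_labels[int(rng.integers(0, len(background_labels)))]
        elif mode == "uniform":
            label = all_labels[int(rng.integers(0, len(all_labels)))]
        else:
            raise ValueError(f"unknown annotation mode {mode!r}")
        out.append(FunctionAnnotation(promoter_id=p.id, environment=p.environment or "synthetic",
                                      function_label=label, source=f"synthetic:{mode}"))
    return out
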