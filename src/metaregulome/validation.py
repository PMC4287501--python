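"""Randomization controls and known-motif comparison.

The principal control shuffles each promoter within consecutive 20-nt
windows — destroying motif instances while preserving local nucleotide
composition — reruns the full discovery on the shuffled set and compares
the per-promoter TFBS count distributions. Predicted sites can also be
matched against a user-supplied library of known regulator consensus
sequences (IUPAC strings, RegPrecise-style).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data.IUPACData import ambiguous_dna_values
from scipy import stats

from .dimers import DiscoveryResult, SiteCall, discover_motifs
from .seqio import SequenceRecord, reverse_complement

__all__ = [
    "KnownMotif",
    "ValidationResult",
    "window_shuffle",
    "shuffle_promoters",
    "shuffled_rediscovery",
    "iupac_regex",
    "scan_known_motifs",
    "read_known_motifs",
]


@dataclass(frozen=True)
class KnownMotif:
    """A known transcription-factor binding consensus (e.g. LexA)."""

    name: str
    consensus: str
    source: str = ""

    def __post_init__(self) -> None:
        if not self.consensus:
            raise ValueError("consensus must be non-empty")
        bad = set(self.consensus.upper()) - set(ambiguous_dna_values)
        if bad:
            raise ValueError(f"motif {self.name!r}: non-IUPAC characters {sorted(bad)}")


def window_shuffle(sequence: str, window_size: int = 20, seed: int | None = None,
                   rng: np.random.Generator | None = None) -> str:
    """Permute bases uniformly within consecutive non-overlapping windows.

    The last window may be short. Per-window base multisets — hence local
    composition — are preserved exactly. Deterministic given the seed.
    """
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    if rng is None:
        if seed is None:
            raise ValueError("a seed (or generator) is required")
        rng = np.random.default_rng(seed)
    chars = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8).copy()
    for start in range(0, len(chars), window_size):
        block = chars[start : start + window_size]
        chars[start : start + window_size] = rng.permutation(block)
    return chars.tobytes().decode("ascii")


def shuffle_promoters(promoters: Sequence[SequenceRecord], window_size: int = 20,
                      seed: int = 0) -> list[SequenceRecord]:
    """Window-shuffle every promoter with one generator stream; ids and
    lengths are conserved."""
    rng = np.random.default_rng(seed)
    out = []
    for p in promoters:
        out.append(SequenceRecord(
            id=p.id, sequence=window_shuffle(p.sequence, window_size, rng=rng),
            description=f"{p.description} [shuffled w={window_size}]".strip(),
            source_read=p.source_read, strand=p.strand, offset=p.offset,
        ))
    return out


@dataclass
class ValidationResult:
    """Real-vs-shuffled rediscovery comparison."""

    real: DiscoveryResult
    shuffled: DiscoveryResult
    real_counts: pd.Series
    shuffled_counts: pd.Series
    u_statistic: float
    p_value: float
    window_size: int
    seed: int
    alpha_reused: bool


def shuffled_rediscovery(
    promoters: Sequence[SequenceRecord],
    seed: int,
    window_size: int = 20,
    reuse_alpha: bool = False,
    **discovery_kwargs,
) -> ValidationResult:
    """Run discovery on the promoters and on their window-shuffled copies.

    Significance on the shuffled set is recomputed from the shuffled data
    (its own N_motif and alpha) by default; ``reuse_alpha=True`` re-applies
    the real-data alpha instead. The two per-promoter TFBS count
    distributions are compared with a two-sided Mann-Whitney U test.
    """
    real = discover_motifs(promoters, **discovery_kwargs)
    shuffled_set = shuffle_promoters(promoters, window_size, seed)
    shuffled = discover_motifs(shuffled_set, **discovery_kwargs)
    if reuse_alpha and real.alpha is not None:
        motifs = shuffled.motifs.copy()
        motifs["significant"] = motifs["p_value"] < real.alpha
        shuffled.motifs = motifs
        shuffled.alpha = real.alpha
        from .dimers import PalindromicDimer, PromoterIndex, promoter_tfbs_counts

        index = PromoterIndex(shuffled_set)
        sites = []
        for _, row in motifs[motifs["significant"]].iterrows():
            sites.extend(index.dimer_sites(PalindromicDimer(w1=row["w1"], spacer=int(row["spacer"]))))
        shuffled.sites = sites
        shuffled.promoter_counts = promoter_tfbs_counts(
            sites, motifs.loc[motifs["significant"], "name"], index.ids,
            mode=discovery_kwargs.get("counting_mode", "distinct_motifs"),
        )
    x = real.promoter_counts.to_numpy()
    y = shuffled.promoter_counts.to_numpy()
    pooled = np.concatenate([x, y])
    if pooled.size == 0 or np.all(pooled == pooled[0]):
        u, p = float(len(x) * len(y) / 2), 1.0
    else:
        u, p = stats.mannwhitneyu(x, y, alternative="two-sided")
    return ValidationResult(
        real=real, shuffled=shuffled,
        real_counts=real.promoter_counts, shuffled_counts=shuffled.promoter_counts,
        u_statistic=float(u), p_value=float(p),
        window_size=window_size, seed=seed, alpha_reused=reuse_alpha,
    )


def iupac_regex(consensus: str) -> re.Pattern:
    """Compile an IUPAC consensus into a regex of character classes.

    A fully degenerate consensus position (N) also matches an N in the
    target; partially degenerate codes match only resolved bases.
    """
    parts = []
    for c in consensus.upper():
        values = ambiguous_dna_values[c]
        if set(values) == set("ACGT"):
            values += "N"
        parts.append(values[0] if len(values) == 1 else f"[{values}]")
    return re.compile("".join(parts))


def _matches(pattern: re.Pattern, text: str) -> int:
    """Occurrences of the consensus on either strand of ``text`` (overlapping)."""
    n = 0
    for t in (text, reverse_complement(text)):
        pos = 0
        while True:
            m = pattern.search(t, pos)
            if m is None:
                break
            n += 1
            pos = m.start() + 1
    return n


@dataclass
class KnownMotifScan:
    """Result of matching predictions against a known-motif library."""

    per_item: pd.DataFrame
    fraction_with_match: float
    env_counts: pd.DataFrame  # environment x known motif occurrence counts


def scan_known_motifs(
    items: Sequence[SiteCall] | Sequence[SequenceRecord],
    known_motifs: Sequence[KnownMotif],
    mode: Literal["sites", "promoters"] = "sites",
) -> KnownMotifScan:
    """Match predicted sites (or whole promoters) against known consensi.

    Both strands are scanned. In ``sites`` mode each predicted site's
    matched text is tested for containing at least one known consensus; the
    overall fraction of sites with a match is the headline number. In
    ``promoters`` mode full promoter sequences are scanned and per
    (environment, motif) occurrence counts are returned, suitable for
    density computation.
    """
    patterns = [(m.name, iupac_regex(m.consensus)) for m in known_motifs]
    rows = []
    env_counts: dict[tuple[str, str], int] = {}
    if mode == "sites":
        for s in items:
            matched = [name for name, pat in patterns if _matches(pat, s.matched) > 0]
            rows.append({
                "promoter_id": s.promoter_id, "start": s.start, "end": s.end,
                "motif_name": s.motif_name, "known_matches": ",".join(matched),
                "has_known_match": bool(matched),
            })
        df = pd.DataFrame(rows, columns=["promoter_id", "start", "end", "motif_name",
                                         "known_matches", "has_known_match"])
        frac = float(df["has_known_match"].mean()) if len(df) else 0.0
    elif mode == "promoters":
        for p in items:
            env = getattr(p, "environment", "") or ""
            any_match = False
            for name, pat in patterns:
                n = _matches(pat, p.sequence)
                if n:
                    any_match = True
                    env_counts[(env, name)] = env_counts.get((env, name), 0) + n
            rows.append({"promoter_id": p.id, "has_known_match": any_match})
        df = pd.DataFrame(rows, columns=["promoter_id", "has_known_match"])
        frac = float(df["has_known_match"].mean()) if len(df) else 0.0
    else:
        raise ValueError(f"unknown scan mode {mode!r}")
    env_df = pd.DataFrame(
        [{"environment": e, "known_motif": m, "n_sites": n} for (e, m), n in sorted(env_counts.items())],
        columns=["environment", "known_motif", "n_sites"],
    )
    return KnownMotifScan(per_item=df, fraction_with_match=frac, env_counts=env_df)


def read_known_motifs(path: str | Path) -> list[KnownMotif]:
    """Read a two-column (name, IUPAC consensus) TSV with header."""
    df = pd.read_csv(path, sep="\t", comment="#")
    cols = [c.lower() for c in df.columns]
    df.columns = cols
    return [KnownMotif(name=str(r["name"]), consensus=str(r["consensus"]))
            for _, r in df.iterrows()]
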