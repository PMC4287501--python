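"""De novo discovery of palindromic dimer motifs under a Poisson background.

A candidate motif is a dimer W1-N^s-W2 where W1 is a 3-5 nt word, W2 is its
reverse complement and the spacer s runs 0-30, so the full pattern is its
own reverse complement and a single-strand scan finds every genomic
instance. For each dimer D the observed copy number n(D) over the pooled
promoter set is compared with its expectation under independently placed
words,

    n_exp(D) = (n(W1) / Leff(|W|)) * (n(W2) / Leff(|W|)) * Leff(D),

where n(W) is the total (overlapping) occurrence count of word W,
Leff(L) = sum_r max(0, L(r) - L + 1) counts the positions where a pattern
of length L can sit, and the upper-tail Poisson probability
P(X >= n(D) | n_exp) scores overrepresentation. A dimer is called
significant when P < 1/N_motif, with N_motif the number of candidate
dimers observed at least once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .seqio import SequenceRecord, reverse_complement

__all__ = [
    "PalindromicDimer",
    "MotifStats",
    "SiteCall",
    "DiscoveryResult",
    "enumerate_candidate_dimers",
    "encode_motif_name",
    "decode_motif_name",
    "PromoterIndex",
    "count_word",
    "count_dimer",
    "effective_length",
    "expected_count",
    "poisson_pvalue",
    "call_significant_motifs",
    "promoter_tfbs_counts",
    "discover_motifs",
]

_BASES = "ACGT"
_ENC = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(_BASES):
    _ENC[ord(_b)] = _i

W_MIN_DEFAULT, W_MAX_DEFAULT = 3, 5
SPACER_MIN_DEFAULT, SPACER_MAX_DEFAULT = 0, 30


@dataclass(frozen=True)
class PalindromicDimer:
    """A candidate motif W1-N^spacer-W2 with W2 = reverse_complement(W1)."""

    w1: str
    spacer: int

    def __post_init__(self) -> None:
        if not (3 <= len(self.w1) <= 5):
            raise ValueError(f"w1 must be 3-5 nt, got {self.w1!r}")
        if set(self.w1) - set(_BASES):
            raise ValueError(f"w1 must be over ACGT, got {self.w1!r}")
        if not (0 <= self.spacer <= 30):
            raise ValueError(f"spacer must be in [0, 30], got {self.spacer}")

    @property
    def w2(self) -> str:
        return reverse_complement(self.w1)

    @property
    def length(self) -> int:
        """Full motif length L(D) = 2|W1| + spacer."""
        return 2 * len(self.w1) + self.spacer

    @property
    def pattern(self) -> str:
        """Expanded IUPAC pattern, e.g. ATCNNNNNNNNNNGAT."""
        return self.w1 + "N" * self.spacer + self.w2

    @property
    def name(self) -> str:
        return encode_motif_name(self)


def encode_motif_name(dimer: PalindromicDimer) -> str:
    """Canonical name ``"<spacer> <|w1|> <w1>"``, e.g. ``"10 3 ATC"``."""
    return f"{dimer.spacer} {len(dimer.w1)} {dimer.w1}"


def decode_motif_name(name: str) -> PalindromicDimer:
    """Invert :func:`encode_motif_name`."""
    parts = name.split()
    if len(parts) != 3:
        raise ValueError(f"malformed motif name {name!r} (want '<spacer> <w> <word>')")
    spacer, w, word = int(parts[0]), int(parts[1]), parts[2]
    if len(word) != w:
        raise ValueError(f"motif name {name!r}: declared word length {w} != {len(word)}")
    return PalindromicDimer(w1=word, spacer=spacer)


def enumerate_candidate_dimers(
    w_min: int = W_MIN_DEFAULT,
    w_max: int = W_MAX_DEFAULT,
    spacer_min: int = SPACER_MIN_DEFAULT,
    spacer_max: int = SPACER_MAX_DEFAULT,
) -> list[PalindromicDimer]:
    """All candidate dimers, ordered by |w1|, then w1, then spacer."""
    if w_min > w_max or spacer_min > spacer_max:
        raise ValueError("empty enumeration range")
    out: list[PalindromicDimer] = []
    for w in range(w_min, w_max + 1):
        for code in range(4 ** w):
            word = _decode_word(code, w)
            for spacer in range(spacer_min, spacer_max + 1):
                out.append(PalindromicDimer(w1=word, spacer=spacer))
    return out


def _decode_word(code: int, w: int) -> str:
    chars = []
    for _ in range(w):
        chars.append(_BASES[code % 4])
        code //= 4
    return "".join(reversed(chars))


def _encode_word(word: str) -> int:
    code = 0
    for c in word:
        code = code * 4 + _BASES.index(c)
    return code


def _rc_code_table(w: int) -> np.ndarray:
    """code -> code of the reverse complement word, for all 4**w words."""
    ids = np.arange(4 ** w, dtype=np.int64)
    rc = np.zeros_like(ids)
    x = ids.copy()
    for _ in range(w):
        rc = rc * 4 + (3 - x % 4)
        x //= 4
    return rc


@dataclass
class MotifStats:
    """Counts and significance for one candidate dimer."""

    dimer: PalindromicDimer
    n_obs: int
    n_w1: int
    n_w2: int
    leff_d: int
    leff_w: int
    n_exp: float
    p_value: float
    significant: bool = False


@dataclass(frozen=True)
class SiteCall:
    """One located instance of a dimer on a promoter (0-based half-open)."""

    promoter_id: str
    start: int
    end: int
    motif_name: str
    matched: str


class PromoterIndex:
    """Integer-encoded promoter set with cached k-word code arrays.

    ``codes(w)[p][i]`` is the base-4 code of the w-mer starting at position
    ``i`` of promoter ``p`` (-1 where an N intervenes); the padded
    concatenation ``pooled(w)`` supports pooled pair histograms without
    cross-promoter artifacts.
    """

    def __init__(self, promoters: Sequence[SequenceRecord]):
        self.ids = [p.id for p in promoters]
        self.lengths = np.array([len(p.sequence) for p in promoters], dtype=np.int64)
        self.sequences = [p.sequence for p in promoters]
        self._encoded = [
            _ENC[np.frombuffer(p.sequence.encode("ascii"), dtype=np.uint8)]
            for p in promoters
        ]
        self._codes: dict[int, list[np.ndarray]] = {}
        self._pooled: dict[int, np.ndarray] = {}

    def __len__(self) -> int:
        return len(self.ids)

    def codes(self, w: int) -> list[np.ndarray]:
        if w not in self._codes:
            self._codes[w] = [self._word_codes(arr, w) for arr in self._encoded]
        return self._codes[w]

    @staticmethod
    def _word_codes(arr: np.ndarray, w: int) -> np.ndarray:
        n = len(arr) - w + 1
        if n <= 0:
            return np.empty(0, dtype=np.int64)
        code = np.zeros(n, dtype=np.int64)
        ok = np.ones(n, dtype=bool)
        for j in range(w):
            seg = arr[j : j + n]
            code = code * 4 + np.maximum(seg, 0)
            ok &= seg >= 0
        code[~ok] = -1
        return code

    def pooled(self, w: int, pad: int = 64) -> np.ndarray:
        """All code arrays concatenated with runs of -1 long enough that no
        start-offset pair within the largest motif spans two promoters."""
        if w not in self._pooled:
            gap = np.full(pad, -1, dtype=np.int64)
            parts: list[np.ndarray] = []
            for c in self.codes(w):
                parts.append(c)
                parts.append(gap)
            self._pooled[w] = np.concatenate(parts) if parts else np.empty(0, dtype=np.int64)
        return self._pooled[w]

    def word_count_table(self, w: int) -> np.ndarray:
        """n(W) for every w-mer W: total overlapping occurrences, pooled."""
        pooled = self.pooled(w)
        valid = pooled[pooled >= 0]
        return np.bincount(valid, minlength=4 ** w)

    def pair_histogram(self, w: int, offset: int) -> np.ndarray:
        """Joint counts of (w-mer at i, w-mer at i+offset) pooled over promoters,
        flattened as code1 * 4**w + code2."""
        pooled = self.pooled(w)
        if offset >= len(pooled):
            return np.zeros(16 ** w, dtype=np.int64)
        c1 = pooled[:-offset]
        c2 = pooled[offset:]
        valid = (c1 >= 0) & (c2 >= 0)
        idx = c1[valid] * (4 ** w) + c2[valid]
        return np.bincount(idx, minlength=16 ** w)

    def dimer_sites(self, dimer: PalindromicDimer) -> list[SiteCall]:
        w = len(dimer.w1)
        offset = w + dimer.spacer
        id1 = _encode_word(dimer.w1)
        id2 = _encode_word(dimer.w2)
        name = dimer.name
        calls: list[SiteCall] = []
        for pid, seq, codes in zip(self.ids, self.sequences, self.codes(w)):
            n = len(codes) - offset
            if n <= 0:
                continue
            hits = np.nonzero((codes[:n] == id1) & (codes[offset : offset + n] == id2))[0]
            for i in hits:
                i = int(i)
                calls.append(SiteCall(pid, i, i + dimer.length, name, seq[i : i + dimer.length]))
        return calls

    def dimer_count(self, dimer: PalindromicDimer) -> int:
        w = len(dimer.w1)
        offset = w + dimer.spacer
        id1 = _encode_word(dimer.w1)
        id2 = _encode_word(dimer.w2)
        total = 0
        for codes in self.codes(w):
            n = len(codes) - offset
            if n > 0:
                total += int(np.count_nonzero((codes[:n] == id1) & (codes[offset : offset + n] == id2)))
        return total


def count_word(promoters: Sequence[SequenceRecord] | PromoterIndex, word: str) -> int:
    """Total overlapping exact occurrences of ``word`` over the promoter set.

    Positions containing N never match (words are over ACGT only, so a plain
    substring scan already guarantees this).
    """
    if set(word) - set(_BASES):
        raise ValueError(f"word must be over ACGT, got {word!r}")
    seqs = promoters.sequences if isinstance(promoters, PromoterIndex) else [p.sequence for p in promoters]
    total = 0
    for seq in seqs:
        start = seq.find(word)
        while start != -1:
            total += 1
            start = seq.find(word, start + 1)
    return total


def count_dimer(
    promoters: Sequence[SequenceRecord] | PromoterIndex, dimer: PalindromicDimer
) -> tuple[int, list[SiteCall]]:
    """Count instances of ``dimer`` (overlaps allowed) and locate each site."""
    index = promoters if isinstance(promoters, PromoterIndex) else PromoterIndex(promoters)
    sites = index.dimer_sites(dimer)
    return len(sites), sites


def effective_length(promoter_lengths: Iterable[int], motif_length: int) -> int:
    """Leff = sum over promoters of max(0, L(r) - motif_length + 1)."""
    if motif_length < 1:
        raise ValueError("motif_length must be >= 1")
    return int(sum(max(0, L - motif_length + 1) for L in promoter_lengths))


def expected_count(
    n_w1: int,
    n_w2: int,
    leff_d: int,
    leff_w: int,
    form: Literal["frequency", "simple"] = "frequency",
) -> float:
    """Expected dimer count under independent word placement.

    ``frequency`` (default): per-position word frequencies multiplied by the
    number of placements, (n_w1/leff_w) * (n_w2/leff_w) * leff_d.
    ``simple``: n_w1 * n_w2 / leff_d, retained for sensitivity analysis.
    """
    if leff_d < 0:
        raise ValueError("leff_d must be >= 0")
    if form == "frequency":
        if leff_w <= 0:
            raise ValueError("leff_w must be > 0")
        return (n_w1 / leff_w) * (n_w2 / leff_w) * leff_d
    if form == "simple":
        return (n_w1 * n_w2 / leff_d) if leff_d > 0 else 0.0
    raise ValueError(f"unknown expected-count form {form!r}")


def poisson_pvalue(n_obs: int, n_exp: float) -> float:
    """Upper-tail Poisson probability P(X >= n_obs | mean n_exp).

    Computed through the regularized incomplete gamma (survival function);
    n_obs = 0 returns exactly 1.
    """
    if n_obs < 0 or n_exp < 0:
        raise ValueError("n_obs and n_exp must be non-negative")
    if n_obs == 0:
        return 1.0
    return float(stats.poisson.sf(n_obs - 1, n_exp))


@dataclass
class DiscoveryResult:
    """Everything the discovery stage produces on one promoter set."""

    motifs: pd.DataFrame
    alpha: float | None
    n_motif: int
    sites: list[SiteCall]
    promoter_counts: pd.Series
    params: dict = field(default_factory=dict)

    @property
    def significant(self) -> pd.DataFrame:
        return self.motifs[self.motifs["significant"]]


def call_significant_motifs(
    motifs: pd.DataFrame, n_motif_rule: Literal["observed", "all"] = "observed"
) -> tuple[pd.DataFrame, float | None, int]:
    """Flag dimers with P < 1/N_motif.

    N_motif is the number of candidate dimers observed at least once
    (``observed``, the default reading of "positive motifs found") or the
    full candidate count (``all``). With N_motif = 0 no motif can be called
    and alpha is undefined.
    """
    if n_motif_rule == "observed":
        n_motif = int((motifs["n_obs"] >= 1).sum())
    elif n_motif_rule == "all":
        n_motif = len(motifs)
    else:
        raise ValueError(f"unknown N_motif rule {n_motif_rule!r}")
    motifs = motifs.copy()
    if n_motif == 0:
        import warnings

        warnings.warn("no candidate dimer observed; alpha undefined", stacklevel=2)
        motifs["significant"] = False
        return motifs, None, 0
    alpha = 1.0 / n_motif
    motifs["significant"] = motifs["p_value"] < alpha
    return motifs, alpha, n_motif


def promoter_tfbs_counts(
    site_calls: Iterable[SiteCall],
    significant_names: Iterable[str],
    promoter_ids: Iterable[str],
    mode: Literal["distinct_motifs", "occurrences"] = "distinct_motifs",
) -> pd.Series:
    """Per-promoter regulatory potential.

    ``distinct_motifs`` counts the number of different significant dimers
    with at least one site in the promoter; ``occurrences`` counts every
    site of a significant dimer. Promoters without sites get 0.
    """
    sig = set(significant_names)
    if mode == "distinct_motifs":
        seen: dict[str, set] = {}
        for s in site_calls:
            if s.motif_name in sig:
                seen.setdefault(s.promoter_id, set()).add(s.motif_name)
        values = {pid: len(motifs) for pid, motifs in seen.items()}
    elif mode == "occurrences":
        values = {}
        for s in site_calls:
            if s.motif_name in sig:
                values[s.promoter_id] = values.get(s.promoter_id, 0) + 1
    else:
        raise ValueError(f"unknown counting mode {mode!r}")
    ids = list(promoter_ids)
    return pd.Series([values.get(pid, 0) for pid in ids], index=ids, dtype=int, name="tfbs_count")


def discover_motifs(
    promoters: Sequence[SequenceRecord],
    *,
    w_min: int = W_MIN_DEFAULT,
    w_max: int = W_MAX_DEFAULT,
    spacer_min: int = SPACER_MIN_DEFAULT,
    spacer_max: int = SPACER_MAX_DEFAULT,
    expected_form: Literal["frequency", "simple"] = "frequency",
    n_motif_rule: Literal["observed", "all"] = "observed",
    counting_mode: Literal["distinct_motifs", "occurrences"] = "distinct_motifs",
    collect_sites: bool = True,
) -> DiscoveryResult:
    """Score every candidate dimer on a promoter set and call significance.

    The scan pools all promoters: word counts n(W), effective lengths and
    the per-(geometry) pair histograms are computed once over the pooled
    set, then every dimer's n(D) is a single histogram lookup. Site lists
    are materialized for significant dimers only (``collect_sites``).
    """
    index = PromoterIndex(promoters)
    lengths = index.lengths
    rows: list[dict] = []
    for w in range(w_min, w_max + 1):
        n_words = 4 ** w
        word_counts = index.word_count_table(w)
        rc = _rc_code_table(w)
        leff_w = effective_length(lengths, w)
        words = [_decode_word(c, w) for c in range(n_words)]
        for spacer in range(spacer_min, spacer_max + 1):
            offset = w + spacer
            motif_len = 2 * w + spacer
            leff_d = effective_length(lengths, motif_len)
            hist = index.pair_histogram(w, offset)
            codes = np.arange(n_words, dtype=np.int64)
            n_obs = hist[codes * n_words + rc[codes]]
            n_w1 = word_counts[codes]
            n_w2 = word_counts[rc[codes]]
            if expected_form == "frequency":
                n_exp = (n_w1 / leff_w) * (n_w2 / leff_w) * leff_d if leff_w > 0 else np.zeros(n_words)
            else:
                with np.errstate(divide="ignore", invalid="ignore"):
                    n_exp = np.where(leff_d > 0, n_w1 * n_w2 / max(leff_d, 1), 0.0)
            pvals = np.where(n_obs == 0, 1.0, stats.poisson.sf(n_obs - 1, n_exp))
            for c in range(n_words):
                rows.append(
                    {
                        "name": f"{spacer} {w} {words[c]}",
                        "spacer": spacer,
                        "w": w,
                        "w1": words[c],
                        "w2": words[rc[c]],
                        "pattern": words[c] + "N" * spacer + words[rc[c]],
                        "n_obs": int(n_obs[c]),
                        "n_w1": int(n_w1[c]),
                        "n_w2": int(n_w2[c]),
                        "leff_d": leff_d,
                        "leff_w": leff_w,
                        "n_exp": float(n_exp[c]),
                        "p_value": float(pvals[c]),
                    }
                )
    motifs = pd.DataFrame(rows)
    # deterministic candidate order: |w1|, w1, spacer
    motifs = motifs.sort_values(["w", "w1", "spacer"], kind="mergesort").reset_index(drop=True)
    motifs, alpha, n_motif = call_significant_motifs(motifs, n_motif_rule)

    sites: list[SiteCall] = []
    if collect_sites:
        sig = motifs[motifs["significant"]]
        for _, row in sig.iterrows():
            sites.extend(index.dimer_sites(PalindromicDimer(w1=row["w1"], spacer=int(row["spacer"]))))
    counts = promoter_tfbs_counts(
        sites, motifs.loc[motifs["significant"], "name"], index.ids, mode=counting_mode
    )
    params = {
        "w_min": w_min, "w_max": w_max, "spacer_min": spacer_min, "spacer_max": spacer_max,
        "expected_form": expected_form, "n_motif_rule": n_motif_rule,
        "counting_mode": counting_mode, "n_promoters": len(index), "alpha": alpha,
        "n_motif": n_motif,
    }
    return DiscoveryResult(motifs=motifs, alpha=alpha, n_motif=n_motif, sites=sites,
                           promoter_counts=counts, params=params)
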