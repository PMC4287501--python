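"""Shared fixtures and independent oracles.

Oracles here must stay independent of the implementation paths they
check: the dimer oracle is a regex-lookahead scan, the exact-test oracle
enumerates hypergeometric tables with math.comb, the rank-test oracles
are permutation/midrank constructions.
"""

from __future__ import annotations

import math
import re

import numpy as np
import pytest

from metaregulome import generate_background_promoters


@pytest.fixture(scope="session")
def background_50():
    return generate_background_promoters(50, length=300, gc_fraction=0.5, seed=1701)


@pytest.fixture(scope="session")
def background_500():
    return generate_background_promoters(500, length=300, gc_fraction=0.5, seed=424242)


def brute_force_dimer_count(sequences, w1, spacer, w2):
    """Regex-with-lookahead occurrence count of w1 . N^spacer . w2 over a
    promoter set; overlapping matches counted, N in the target never
    matches (the spacer positions are wildcards that still exclude the
    'X' separator used to join promoters)."""
    pattern = re.compile(f"(?=({re.escape(w1)}[ACGTN]{{{spacer}}}{re.escape(w2)}))")
    joined = "X".join(sequences)
    return sum(1 for _ in pattern.finditer(joined))


def hypergeom_tail_oracle(a, b, c, d):
    """One-sided enrichment p by direct enumeration: P(A >= a) for the
    hypergeometric cell count with all margins fixed."""
    n_total = a + b + c + d
    row1 = a + b
    col1 = a + c
    denom = math.comb(n_total, row1)
    lo = max(0, row1 + col1 - n_total)
    hi = min(row1, col1)
    p = 0.0
    for k in range(a, hi + 1):
        p += math.comb(col1, k) * math.comb(n_total - col1, row1 - k) / denom
    return p


def fisher_two_sided_oracle(a, b, c, d):
    """Two-sided exact p: sum of probabilities of all same-margin tables no
    more likely than the observed one."""
    n_total = a + b + c + d
    row1 = a + b
    col1 = a + c
    denom = math.comb(n_total, row1)
    lo = max(0, row1 + col1 - n_total)
    hi = min(row1, col1)
    probs = {k: math.comb(col1, k) * math.comb(n_total - col1, row1 - k) / denom
             for k in range(lo, hi + 1)}
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-9))


def kruskal_h_oracle(groups):
    """H from first principles via midranks (tie-corrected)."""
    flat = np.concatenate([np.asarray(g, float) for g in groups])
    order = np.argsort(flat, kind="mergesort")
    ranks = np.empty(len(flat))
    ranks[order] = np.arange(1, len(flat) + 1)
    # midranks for ties
    for v in np.unique(flat):
        mask = flat == v
        ranks[mask] = ranks[mask].mean()
    n = len(flat)
    h = 12 / (n * (n + 1)) * sum(
        len(g) * (ranks[idx].mean()) ** 2
        for g, idx in zip(groups, _group_slices(groups))
    ) - 3 * (n + 1)
    # tie correction
    _, counts = np.unique(flat, return_counts=True)
    tie = 1 - (counts ** 3 - counts).sum() / (n ** 3 - n)
    return h / tie


def _group_slices(groups):
    start = 0
    for g in groups:
        yield slice(start, start + len(g))
        start += len(g)


def spearman_oracle(x, y):
    """Pearson correlation of midranks."""
    def midranks(v):
        v = np.asarray(v, float)
        order = np.argsort(v, kind="mergesort")
        r = np.empty(len(v))
        r[order] = np.arange(1, len(v) + 1)
        for u in np.unique(v):
            m = v == u
            r[m] = r[m].mean()
        return r

    rx, ry = midranks(x), midranks(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def iupac_expand(consensus):
    """All concrete ACGT words matching an IUPAC consensus."""
    from Bio.Data.IUPACData import ambiguous_dna_values

    words = [""]
    for c in consensus.upper():
        words = [w + b for w in words for b in ambiguous_dna_values[c]]
    return words
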