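"""Downstream regulatory-potential statistics.

Promoters are ranked by their TFBS count ("regulatory potential"), sliced
into top-k% groups, and each group is tested for functional enrichment
with one-sided exact tests and a Bonferroni family correction; enriched
functions are then compared across environments, known-TFBS densities
across environments with Kruskal-Wallis, and sharing-vs-potential
association with Spearman rank correlation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FunctionAnnotation",
    "DensityRecord",
    "EnrichmentRecord",
    "metagenome_density",
    "rank_and_bin",
    "fisher_enrichment",
    "cross_environment_fisher",
    "kruskal_wallis_density",
    "cooccurrence_by_bin",
    "rank_correlation",
]

LEVEL_SEPARATOR = ";"
DEFAULT_PERCENTS = (1, 5, 10, 20, 30, 40)


@dataclass(frozen=True)
class FunctionAnnotation:
    """A SEED-style functional label for the gene downstream of a promoter.

    ``function_label`` may encode a hierarchy path with ``;`` separators
    ("Carbohydrates;Central carbohydrate metabolism"); each prefix is a
    testable level.
    """

    promoter_id: str
    environment: str
    function_label: str
    source: str = ""

    def levels(self) -> list[str]:
        parts = self.function_label.split(LEVEL_SEPARATOR)
        return [LEVEL_SEPARATOR.join(parts[: i + 1]) for i in range(len(parts))]


@dataclass
class DensityRecord:
    """TFBS density of one metagenome: sites / (promoters x promoter length)."""

    environment: str
    tfbs: str
    n_sites: int
    n_promoters: int
    promoter_length: int
    density: float


@dataclass
class EnrichmentRecord:
    """One group x function exact-test result with its full 2x2 table."""

    group: str
    function_label: str
    level: int
    a: int  # in group, has function
    b: int  # in group, lacks function
    c: int  # out of group, has function
    d: int  # out of group, lacks function
    odds_direction: str
    p_raw: float
    p_bonferroni: float
    significant: bool


def metagenome_density(
    n_sites: int, n_promoters: int, promoter_length: int = 300,
    environment: str = "", tfbs: str = "all",
) -> DensityRecord:
    """Density D(x) = n_sites / (N * Tbp), in sites per base pair."""
    if n_promoters < 1:
        raise ValueError("n_promoters must be >= 1")
    if promoter_length < 1:
        raise ValueError("promoter_length must be >= 1")
    if n_sites < 0:
        raise ValueError("n_sites must be >= 0")
    return DensityRecord(
        environment=environment, tfbs=tfbs, n_sites=n_sites,
        n_promoters=n_promoters, promoter_length=promoter_length,
        density=n_sites / (n_promoters * promoter_length),
    )


def rank_and_bin(
    promoter_counts: Mapping[str, int] | pd.Series,
    percent_list: Sequence[float] = DEFAULT_PERCENTS,
) -> tuple[dict[str, set[str]], dict[str, str]]:
    """Slice promoters by descending TFBS count into top-k% groups and tertiles.

    The top-k% group is the smallest descending-count prefix holding at
    least ceil(k*n/100) promoters, extended over ties at the boundary
    count, so membership depends only on the counts (permutation
    invariant) and groups are nested across increasing k. The second
    return value assigns each promoter a coarse low/medium/high bin by
    count tertiles (boundary ties fall in the lower bin).
    """
    items = dict(promoter_counts)
    if not items:
        raise ValueError("empty promoter count input")
    n = len(items)
    counts = np.array(sorted(items.values(), reverse=True))
    groups: dict[str, set[str]] = {}
    for k in percent_list:
        m = math.ceil(k * n / 100)
        m = max(1, min(m, n))
        boundary = counts[m - 1]
        groups[f"top{k:g}pct"] = {pid for pid, c in items.items() if c >= boundary}
    q1, q2 = np.quantile(counts, [1 / 3, 2 / 3])
    tertiles = {
        pid: ("low" if c <= q1 else "medium" if c <= q2 else "high")
        for pid, c in items.items()
    }
    return groups, tertiles


def _hypergeom_greater(a: int, b: int, c: int, d: int) -> float:
    """One-sided (enrichment) exact p for a 2x2 table: P(A >= a) with
    margins fixed, A hypergeometric."""
    return float(stats.hypergeom.sf(a - 1, a + b + c + d, a + c, a + b))


def fisher_enrichment(
    groups: Mapping[str, Iterable[str]],
    annotations: Sequence[FunctionAnnotation],
    alpha: float = 0.05,
) -> list[EnrichmentRecord]:
    """Exact one-sided enrichment of each function inside each top group.

    For every group and every function observed at any hierarchy level, a
    2x2 table of in-group/out-group x has/lacks-function is built over the
    annotated promoters, the one-sided hypergeometric tail gives the raw p,
    and Bonferroni corrects across the functions tested within one
    (group, level) family.
    """
    ann_by_prom = {a.promoter_id: a for a in annotations}
    universe = set(ann_by_prom)
    if not universe:
        return []
    # function -> (level, set of promoters carrying it)
    func_proms: dict[str, set[str]] = {}
    func_level: dict[str, int] = {}
    for a in annotations:
        for lvl, label in enumerate(a.levels()):
            func_proms.setdefault(label, set()).add(a.promoter_id)
            func_level[label] = lvl

    records: list[EnrichmentRecord] = []
    for gname, members in groups.items():
        in_group = set(members) & universe
        if not in_group:
            continue
        out_group = universe - in_group
        # family size per level for Bonferroni
        by_level: dict[int, list[str]] = {}
        for label, lvl in func_level.items():
            by_level.setdefault(lvl, []).append(label)
        for lvl, labels in sorted(by_level.items()):
            n_tests = len(labels)
            for label in sorted(labels):
                carriers = func_proms[label]
                a_ = len(in_group & carriers)
                b_ = len(in_group) - a_
                c_ = len(out_group & carriers)
                d_ = len(out_group) - c_
                p = _hypergeom_greater(a_, b_, c_, d_)
                p_bonf = min(1.0, p * n_tests)
                expected = len(in_group) * len(carriers) / len(universe)
                records.append(
                    EnrichmentRecord(
                        group=gname, function_label=label, level=lvl,
                        a=a_, b=b_, c=c_, d=d_,
                        odds_direction="enriched" if a_ > expected else "depleted_or_flat",
                        p_raw=p, p_bonferroni=p_bonf,
                        significant=p_bonf < alpha,
                    )
                )
    return records


def cross_environment_fisher(
    env_a_group: Iterable[str],
    env_b_group: Iterable[str],
    function_promoters: Iterable[str],
    labels: tuple[str, str] = ("env_a", "env_b"),
) -> EnrichmentRecord:
    """Two-sided exact test: is a function's prevalence maintained between the
    top groups of two environments?

    The 2x2 table is environment x has/lacks-function restricted to the two
    groups. A zero margin makes the test degenerate: p = 1 with a note.
    """
    ga, gb = set(env_a_group), set(env_b_group)
    if not ga or not gb:
        raise ValueError("both groups must be non-empty")
    carriers = set(function_promoters)
    a = len(ga & carriers)
    b = len(ga) - a
    c = len(gb & carriers)
    d = len(gb) - c
    note = "ok"
    if (a + c) == 0 or (b + d) == 0:
        p = 1.0
        note = "degenerate_margin"
    else:
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return EnrichmentRecord(
        group=f"{labels[0]}_vs_{labels[1]}", function_label=note, level=0,
        a=a, b=b, c=c, d=d,
        odds_direction="two_sided", p_raw=float(p),
        p_bonferroni=float(p), significant=False,
    )


def kruskal_wallis_density(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Kruskal-Wallis H (midrank tie correction) with chi-square asymptotic p.

    Used to compare a known TFBS's per-promoter density between
    environments. All observations identical returns (0, 1) by convention.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("every group needs at least one observation")
    flat = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.all(flat == flat[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


@dataclass
class CooccurrenceResult:
    """Function sharing across environments, stratified by regulatory bin."""

    table: pd.DataFrame  # index: bin, columns: n environments sharing
    rho: float | None
    p_value: float | None
    note: str


def cooccurrence_by_bin(
    annotations_by_environment: Mapping[str, Mapping[str, str]],
    bins: Mapping[str, str],
    promoter_counts: Mapping[str, int],
) -> CooccurrenceResult:
    """How widely shared are the functions in each regulatory bin?

    For every regulatory bin (low/medium/high), counts distinct
    (environment, function) assignments by how many environments carry that
    function at all (presence/absence). The association statistic is the
    Spearman rank correlation between each annotated promoter's TFBS count
    and the number of environments sharing its function.
    """
    envs = list(annotations_by_environment)
    if len(envs) < 2:
        raise ValueError("co-occurrence requires at least two environments")
    func_envs: dict[str, set[str]] = {}
    for env, ann in annotations_by_environment.items():
        for func in ann.values():
            func_envs.setdefault(func, set()).add(env)

    triples: set[tuple[str, str, str]] = set()
    for env, ann in annotations_by_environment.items():
        for pid, func in ann.items():
            if pid in bins:
                triples.add((env, func, bins[pid]))
    bin_order = ["low", "medium", "high"]
    share_range = range(1, len(envs) + 1)
    table = pd.DataFrame(0, index=bin_order, columns=list(share_range))
    for env, func, b in triples:
        table.loc[b, len(func_envs[func])] += 1

    xs: list[int] = []
    ys: list[int] = []
    for env, ann in annotations_by_environment.items():
        for pid, func in ann.items():
            if pid in promoter_counts:
                xs.append(promoter_counts[pid])
                ys.append(len(func_envs[func]))
    if len(xs) < 3 or len(set(xs)) == 1 or len(set(ys)) == 1:
        warnings.warn("constant vector: sharing correlation undefined", stacklevel=2)
        return CooccurrenceResult(table=table, rho=None, p_value=None, note="constant_vector")
    rho, p = stats.spearmanr(xs, ys)
    return CooccurrenceResult(table=table, rho=float(rho), p_value=float(p), note="ok")


def rank_correlation(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rho via midranks with t-approximation p.

    Used e.g. to compare two per-promoter site-count vectors from different
    prediction methods. Constant input is undefined and raises.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("rank correlation undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)
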