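"""Density, ranking, exact-test enrichment and rank statistics."""

import numpy as np
import pytest

from metaregulome import (
    FunctionAnnotation,
    cooccurrence_by_bin,
    cross_environment_fisher,
    fisher_enrichment,
    kruskal_wallis_density,
    metagenome_density,
    rank_and_bin,
    rank_correlation,
)
from metaregulome.regstats import _hypergeom_greater

from conftest import fisher_two_sided_oracle, hypergeom_tail_oracle, kruskal_h_oracle, spearman_oracle


class TestDensity:
    def test_toy_value(self):
        rec = metagenome_density(30, 10, 300)
        assert rec.density == pytest.approx(0.01)

    def test_zero_sites(self):
        assert metagenome_density(0, 10, 300).density == 0.0

    def test_homogeneity_under_duplication(self):
        a = metagenome_density(30, 10, 300)
        b = metagenome_density(60, 20, 300)
        assert a.density == pytest.approx(b.density)

    def test_zero_promoters_rejected(self):
        with pytest.raises(ValueError):
            metagenome_density(5, 0, 300)


class TestRankAndBin:
    def test_top20_no_tie(self):
        counts = {"a": 5, "b": 4, "c": 3, "d": 2, "e": 1}
        groups, _ = rank_and_bin(counts, percent_list=[20])
        assert groups["top20pct"] == {"a"}

    def test_tie_extension_at_boundary(self):
        counts = {"a": 5, "b": 5, "c": 3, "d": 2, "e": 1}
        groups, _ = rank_and_bin(counts, percent_list=[20])
        assert groups["top20pct"] == {"a", "b"}

    def test_permutation_invariance(self):
        rng = np.random.default_rng(8)
        counts = {f"p{i}": int(rng.integers(0, 20)) for i in range(60)}
        groups1, tert1 = rank_and_bin(counts)
        shuffled = dict(sorted(counts.items(), key=lambda kv: rng.random()))
        groups2, tert2 = rank_and_bin(shuffled)
        assert groups1 == groups2 and tert1 == tert2

    def test_groups_nested_in_k(self):
        rng = np.random.default_rng(9)
        counts = {f"p{i}": int(rng.integers(0, 50)) for i in range(200)}
        groups, _ = rank_and_bin(counts)
        ks = [1, 5, 10, 20, 30, 40]
        for k_small, k_big in zip(ks, ks[1:]):
            assert groups[f"top{k_small}pct"] <= groups[f"top{k_big}pct"]

    def test_tertiles_cover_everyone(self):
        counts = {f"p{i}": i for i in range(9)}
        _, tert = rank_and_bin(counts)
        assert set(tert) == set(counts)
        assert set(tert.values()) == {"low", "medium", "high"}

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            rank_and_bin({})


class TestFisherEnrichment:
    def test_minimal_table(self):
        assert _hypergeom_greater(1, 0, 0, 1) == pytest.approx(0.5)

    def test_expectation_table_not_enriched(self):
        # a exactly at its margin expectation: one-sided p must be >= 0.5
        assert _hypergeom_greater(5, 5, 5, 5) >= 0.5

    def test_matches_enumeration_oracle_all_small_tables(self):
        for n in range(2, 31, 4):
            for row1 in range(1, n):
                for col1 in range(0, n + 1, 3):
                    lo = max(0, row1 + col1 - n)
                    hi = min(row1, col1)
                    for a in range(lo, hi + 1):
                        b = row1 - a
                        c = col1 - a
                        d = n - row1 - c
                        assert _hypergeom_greater(a, b, c, d) == pytest.approx(
                            hypergeom_tail_oracle(a, b, c, d), rel=1e-9
                        )

    def test_constructed_enrichment_found(self):
        annotations = [
            FunctionAnnotation(f"p{i}", "env", "F;F1" if i < 10 else "G;G1")
            for i in range(100)
        ]
        groups = {"top10pct": {f"p{i}" for i in range(10)}}
        records = fisher_enrichment(groups, annotations)
        best = {r.function_label: r for r in records}
        assert best["F"].a == 10 and best["F"].b == 0
        assert best["F"].p_bonferroni < 0.05 and best["F"].significant

    def test_bonferroni_never_decreases(self):
        annotations = [
            FunctionAnnotation(f"p{i}", "env", ["A", "B", "C"][i % 3]) for i in range(30)
        ]
        groups = {"g": {f"p{i}" for i in range(10)}}
        for r in fisher_enrichment(groups, annotations):
            assert r.p_bonferroni >= r.p_raw


class TestCrossEnvironmentFisher:
    def test_identical_composition(self):
        rec = cross_environment_fisher(
            [f"a{i}" for i in range(10)], [f"b{i}" for i in range(10)],
            [f"a{i}" for i in range(5)] + [f"b{i}" for i in range(5)],
        )
        assert rec.p_raw == pytest.approx(1.0)

    def test_perfect_separation(self):
        a_ids = [f"a{i}" for i in range(10)]
        b_ids = [f"b{i}" for i in range(10)]
        rec = cross_environment_fisher(a_ids, b_ids, a_ids)
        expected = fisher_two_sided_oracle(10, 0, 0, 10)
        assert rec.p_raw == pytest.approx(expected, rel=1e-6)
        assert rec.p_raw == pytest.approx(1.082e-5, rel=5e-3)

    def test_symmetric_under_environment_swap(self):
        a_ids = [f"a{i}" for i in range(8)]
        b_ids = [f"b{i}" for i in range(12)]
        func = a_ids[:5] + b_ids[:3]
        r1 = cross_environment_fisher(a_ids, b_ids, func)
        r2 = cross_environment_fisher(b_ids, a_ids, func)
        assert r1.p_raw == pytest.approx(r2.p_raw)

    def test_zero_margin_degenerate(self):
        rec = cross_environment_fisher(["a1"], ["b1"], [])
        assert rec.p_raw == 1.0 and rec.function_label == "degenerate_margin"

    def test_matches_two_sided_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            na, nb = int(rng.integers(2, 12)), int(rng.integers(2, 12))
            a_ids = [f"a{i}" for i in range(na)]
            b_ids = [f"b{i}" for i in range(nb)]
            func = [x for x in a_ids + b_ids if rng.random() < 0.4]
            if not func or len(func) == na + nb:
                continue
            rec = cross_environment_fisher(a_ids, b_ids, func)
            assert rec.p_raw == pytest.approx(
                fisher_two_sided_oracle(rec.a, rec.b, rec.c, rec.d), rel=1e-6
            )


class TestKruskalWallis:
    def test_closed_form_three_groups(self):
        h, p = kruskal_wallis_density([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert h == pytest.approx(7.2)

    def test_identical_groups(self):
        h, p = kruskal_wallis_density([[1, 2, 3], [1, 2, 3]])
        assert h == pytest.approx(0.0, abs=1e-12)

    def test_all_constant_convention(self):
        h, p = kruskal_wallis_density([[2, 2], [2, 2, 2]])
        assert (h, p) == (0.0, 1.0)

    def test_matches_rank_oracle_with_ties(self):
        groups = [[1.0, 2.0, 2.0, 5.0, 7.0], [2.0, 3.0, 3.0, 8.0, 9.0], [1.0, 4.0, 6.0, 6.0, 10.0]]
        h, _ = kruskal_wallis_density(groups)
        assert h == pytest.approx(kruskal_h_oracle(groups), rel=1e-9)

    def test_matches_permutation_oracle(self):
        groups = [[1.2, 3.4, 2.2, 5.1, 0.3], [4.4, 6.1, 5.5, 7.2, 3.3], [2.1, 8.8, 7.7, 6.6, 9.9]]
        h_obs, p_asym = kruskal_wallis_density(groups)
        rng = np.random.default_rng(17)
        n = 15
        sizes = [5, 5, 5]
        n_perm = 100_000
        # values are distinct, so a label permutation is a permutation of the
        # ranks 1..15 and H reduces to the rank-sum formula
        perms = np.argsort(rng.random((n_perm, n)), axis=1) + 1.0
        start = 0
        h_perm = np.zeros(n_perm)
        for s in sizes:
            h_perm += perms[:, start : start + s].sum(axis=1) ** 2 / s
            start += s
        h_perm = 12.0 / (n * (n + 1)) * h_perm - 3 * (n + 1)
        p_perm = float(np.mean(h_perm >= h_obs - 1e-12))
        # asymptotic chi-square p agrees with the permutation null within
        # Monte-Carlo error plus a small finite-sample allowance at n = 15
        assert abs(p_perm - p_asym) <= 3 * np.sqrt(p_perm * (1 - p_perm) / n_perm) + 0.02

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis_density([[1, 2, 3]])


class TestCooccurrence:
    def _setup(self, shared_low=True):
        # high-bin promoters carry environment-unique functions, low-bin
        # promoters a function shared by all environments
        envs = ["e1", "e2", "e3"]
        ann = {}
        counts = {}
        bins = {}
        for e in envs:
            ann[e] = {}
            for i in range(6):
                pid = f"{e}_p{i}"
                if i < 3:
                    ann[e][pid] = "shared"
                    counts[pid] = 1
                    bins[pid] = "low"
                else:
                    ann[e][pid] = f"unique_{e}_{i}"
                    counts[pid] = 10 + i
                    bins[pid] = "high"
        return ann, bins, counts

    def test_constructed_negative_correlation(self):
        ann, bins, counts = self._setup()
        res = cooccurrence_by_bin(ann, bins, counts)
        assert res.rho is not None and res.rho < 0

    def test_contingency_conservation(self):
        ann, bins, counts = self._setup()
        res = cooccurrence_by_bin(ann, bins, counts)
        triples = {(e, f, bins[p]) for e, d in ann.items() for p, f in d.items()}
        assert int(res.table.to_numpy().sum()) == len(triples)

    def test_degenerate_constant_sharing(self):
        ann = {"e1": {"p1": "F"}, "e2": {"p2": "F"}}
        counts = {"p1": 1, "p2": 2}
        bins = {"p1": "low", "p2": "high"}
        with pytest.warns(UserWarning):
            res = cooccurrence_by_bin(ann, bins, counts)
        assert res.rho is None and res.note == "constant_vector"

    def test_single_environment_rejected(self):
        with pytest.raises(ValueError):
            cooccurrence_by_bin({"e1": {"p1": "F"}}, {"p1": "low"}, {"p1": 1})


class TestRankCorrelation:
    def test_perfect_agreement(self):
        assert rank_correlation([1, 2, 3, 4], [10, 20, 30, 40])[0] == pytest.approx(1.0)

    def test_perfect_reversal(self):
        assert rank_correlation([1, 2, 3, 4], [8, 6, 4, 2])[0] == pytest.approx(-1.0)

    def test_matches_pearson_on_midranks_oracle(self):
        rng = np.random.default_rng(21)
        x = rng.integers(0, 15, size=100).astype(float)
        y = x + rng.normal(0, 4, size=100)
        rho, _ = rank_correlation(x, y)
        assert rho == pytest.approx(spearman_oracle(x, y), rel=1e-9)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            rank_correlation([1, 1, 1], [1, 2, 3])
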