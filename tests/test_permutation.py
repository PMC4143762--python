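"""Permutation schemes, conservation laws, p-value estimator."""

import itertools

import numpy as np
import pytest

from pbiscan import (
    PedigreePhenotypes,
    PermutationPlan,
    derive_seed,
    gxe_permutation_pvalue,
    gxe_scores,
    permutation_pvalue,
    permute_global,
    permute_local,
    permute_residual,
)


class TestPedigreePhenotypes:
    def test_residuals_sum_to_zero_within_pedigree(self, rng):
        y = rng.normal(100, 15, size=60)
        peds = rng.integers(0, 6, size=60)
        ped = PedigreePhenotypes.from_arrays(y, peds)
        for idx in ped.groups:
            assert abs(ped.residuals[idx].sum()) <= 1e-9 * max(1.0, abs(y[idx]).sum())

    def test_ped_means_reproduce_from_y(self, rng):
        y = rng.normal(size=30)
        peds = np.repeat(np.arange(5), 6)
        ped = PedigreePhenotypes.from_arrays(y, peds)
        for i, idx in enumerate(ped.groups):
            assert ped.ped_means[i] == pytest.approx(y[idx].mean(), rel=1e-12)


class TestSchemes:
    def test_global_preserves_multiset(self, rng):
        y = rng.normal(size=50)
        out = permute_global(y, rng)
        np.testing.assert_allclose(np.sort(out), np.sort(y))

    def test_global_single_subject_identity(self, rng):
        np.testing.assert_array_equal(permute_global(np.array([7.0]), rng), [7.0])

    def test_global_orderings_uniform(self, rng):
        # all 6 orderings of [1,2,3] within 3 standard errors of 1/6
        counts = {}
        for _ in range(10_000):
            key = tuple(permute_global(np.array([1.0, 2.0, 3.0]), rng))
            counts[key] = counts.get(key, 0) + 1
        assert set(counts) == set(itertools.permutations((1.0, 2.0, 3.0)))
        se = np.sqrt((1 / 6) * (5 / 6) / 10_000)
        for c in counts.values():
            assert abs(c / 10_000 - 1 / 6) <= 3 * se

    def test_local_preserves_per_pedigree_multisets(self, rng):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        peds = np.array([1, 1, 2, 2])
        for _ in range(20):
            out = permute_local(y, peds, rng)
            assert set(out[:2]) == {1.0, 2.0}
            assert set(out[2:]) == {3.0, 4.0}

    def test_local_per_pedigree_means_exact(self, rng):
        y = rng.normal(size=40)
        peds = rng.integers(0, 5, size=40)
        out = permute_local(y, peds, rng)
        for p in np.unique(peds):
            assert out[peds == p].mean() == pytest.approx(y[peds == p].mean(), rel=1e-14)

    def test_local_singleton_pedigrees_identity(self, rng):
        y = rng.normal(size=8)
        out = permute_local(y, np.arange(8), rng)
        np.testing.assert_array_equal(out, y)

    def test_residual_singleton_pedigrees_identity(self, rng):
        y = rng.normal(size=8)
        out = permute_residual(y, np.arange(8), rng)
        np.testing.assert_allclose(out, y)

    def test_residual_reconstruction_enumerated(self, rng):
        # pedigrees [1,1,2,2], y=[1,3,10,14]: means 2 and 12, residuals
        # [-1,1,-2,2]; every draw must be ped-mean + some residual ordering
        y = np.array([1.0, 3.0, 10.0, 14.0])
        peds = np.array([1, 1, 2, 2])
        fitted = np.array([2.0, 2.0, 12.0, 12.0])
        valid = {
            tuple(fitted + np.array(p))
            for p in itertools.permutations((-1.0, 1.0, -2.0, 2.0))
        }
        assert (4.0, 0.0, 13.0, 11.0) in valid  # the hand-derived example
        seen = set()
        for _ in range(200):
            seen.add(tuple(permute_residual(y, peds, rng)))
        assert seen <= valid
        assert len(seen) > 1

    def test_residual_preserves_grand_sum(self, rng):
        y = rng.normal(50, 20, size=35)
        peds = rng.integers(0, 4, size=35)
        out = permute_residual(y, peds, rng)
        assert out.sum() == pytest.approx(y.sum(), rel=1e-9)


class TestPValue:
    def _stat(self, g, e):
        return lambda yb: gxe_scores(yb, g, e).i_gxe

    def test_add_one_lower_bound(self, rng):
        # observed above every permuted statistic at B=999 gives 1/1000
        y = rng.normal(size=20)
        plan = PermutationPlan(scheme="global", B=999, seed=1)
        p = permutation_pvalue(np.inf, lambda yb: 0.0, y, plan=plan)
        assert p == pytest.approx(1 / 1000)

    def test_minimum_statistic_gives_one(self, rng):
        y = rng.normal(size=20)
        plan = PermutationPlan(scheme="global", B=99, seed=1)
        p = permutation_pvalue(-np.inf, lambda yb: 0.0, y, plan=plan)
        assert p == 1.0

    @pytest.mark.parametrize("scheme", ["global", "local", "residual"])
    def test_reproducible_and_in_range(self, scheme, rng):
        y = rng.normal(size=30)
        g = rng.integers(0, 3, size=30)
        e = rng.integers(0, 3, size=30)
        peds = np.repeat(np.arange(5), 6)
        obs = gxe_scores(y, g, e).i_gxe
        plan = PermutationPlan(scheme=scheme, B=199, seed=7)
        p1 = permutation_pvalue(obs, self._stat(g, e), y, peds, plan)
        p2 = permutation_pvalue(obs, self._stat(g, e), y, peds, plan)
        assert p1 == p2
        assert 1 / 200 <= p1 <= 1.0

    @pytest.mark.parametrize("scheme", ["global", "local", "residual"])
    def test_fast_path_matches_generic(self, scheme, rng):
        y = rng.normal(size=36)
        g = rng.integers(0, 3, size=36)
        e = rng.integers(0, 3, size=36)
        peds = np.repeat(np.arange(6), 6)
        obs = gxe_scores(y, g, e).i_gxe
        plan = PermutationPlan(scheme=scheme, B=149, seed=13)
        p_slow = permutation_pvalue(obs, self._stat(g, e), y, peds, plan)
        p_fast = gxe_permutation_pvalue(y, g, e, obs, peds, plan)
        assert p_slow == p_fast

    def test_failing_statistic_counts_conservatively(self, rng):
        calls = {"n": 0}

        def bad_stat(yb):
            calls["n"] += 1
            raise ValueError("degenerate")

        y = rng.normal(size=10)
        plan = PermutationPlan(scheme="global", B=9, seed=0)
        p = permutation_pvalue(1.0, bad_stat, y, plan=plan)
        assert p == 1.0  # every failed draw counted as an exceedance
        assert calls["n"] == 18  # each draw retried once

    def test_schemes_coincide_for_singleton_pedigrees(self, rng):
        # with every pedigree of size 1, local and residual leave y fixed,
        # so their p-values are the degenerate all-ties value
        y = rng.normal(size=12)
        g = rng.integers(0, 2, size=12)
        e = rng.integers(0, 2, size=12)
        obs = gxe_scores(y, g, e).i_gxe
        peds = np.arange(12)
        for scheme in ("local", "residual"):
            plan = PermutationPlan(scheme=scheme, B=19, seed=3)
            assert permutation_pvalue(obs, self._stat(g, e), y, peds, plan) == 1.0

    def test_invalid_plan_rejected(self):
        with pytest.raises(ValueError):
            PermutationPlan(scheme="bootstrap")
        with pytest.raises(ValueError):
            PermutationPlan(B=0)


class TestSeedDerivation:
    def test_distinct_contexts_distinct_streams(self):
        a = np.random.default_rng(derive_seed(1, 5, "medicine", "global")).random(4)
        b = np.random.default_rng(derive_seed(1, 5, "medicine", "local")).random(4)
        c = np.random.default_rng(derive_seed(1, 6, "medicine", "global")).random(4)
        assert not np.allclose(a, b) and not np.allclose(a, c)

    def test_same_context_same_stream(self):
        a = np.random.default_rng(derive_seed(2, 0, "age", "residual")).random(4)
        b = np.random.default_rng(derive_seed(2, 0, "age", "residual")).random(4)
        np.testing.assert_array_equal(a, b)
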