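"""Linear-model comparator, Bonferroni threshold, and the scan driver."""

import io as _io

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pbiscan import (
    RankDeficientDesignError,
    bonferroni_threshold,
    lrm_interaction_test,
    run_scan,
    write_results,
)
from pbiscan.simulate import SimConfig, simulate_cohort


class TestLRM:
    def test_exact_additive_data_zero_interaction(self, rng):
        g = rng.integers(0, 3, size=40).astype(float)
        e = rng.integers(0, 3, size=40).astype(float)
        y = 1 + 2 * g + 3 * e
        fit = lrm_interaction_test(y, g, e)
        assert fit.beta[3] == pytest.approx(0.0, abs=1e-8)

    def test_exact_interaction_data(self, rng):
        g = rng.integers(0, 3, size=40).astype(float)
        e = rng.integers(0, 3, size=40).astype(float)
        y = g * e
        fit = lrm_interaction_test(y, g, e)
        assert fit.beta[3] == pytest.approx(1.0, abs=1e-8)
        resid = y - (fit.beta[0] + fit.beta[1] * g + fit.beta[2] * e
                     + fit.beta[3] * g * e)
        assert np.sum(resid**2) == pytest.approx(0.0, abs=1e-12)

    def test_matches_textbook_normal_equations(self):
        # fixed 12-subject dataset scored by hand-rolled OLS: beta =
        # (X'X)^-1 X'y, t = b3/se3 against t(n-4)
        g = np.array([0, 0, 0, 1, 1, 1, 2, 2, 2, 0, 1, 2], dtype=float)
        e = np.array([0, 1, 2, 0, 1, 2, 0, 1, 2, 1, 0, 2], dtype=float)
        y = np.array([3.1, 4.0, 5.2, 2.8, 5.1, 7.3, 2.2, 6.0, 9.9, 4.4, 3.0, 10.2])
        X = np.column_stack([np.ones(12), g, e, g * e])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        sigma2 = resid @ resid / (12 - 4)
        cov = sigma2 * np.linalg.inv(X.T @ X)
        t3 = beta[3] / np.sqrt(cov[3, 3])
        p3 = 2 * stats.t.sf(abs(t3), 12 - 4)
        fit = lrm_interaction_test(y, g, e)
        np.testing.assert_allclose(fit.beta, beta, rtol=1e-10)
        assert fit.p3 == pytest.approx(p3, rel=1e-10)

    def test_rank_deficient_design_raises(self, rng):
        g = rng.integers(0, 3, size=20).astype(float)
        e = np.ones(20)  # constant environment: e column collinear with 1
        with pytest.raises(RankDeficientDesignError):
            lrm_interaction_test(rng.normal(size=20), g, e)


class TestBonferroni:
    def test_chromosome_scale_threshold(self):
        thr = bonferroni_threshold(62_915, 0.05)
        assert thr == pytest.approx(0.05 / 62_915)
        assert float(f"{thr:.1e}") == pytest.approx(7.9e-7)

    @pytest.mark.parametrize("n, alpha, expected", [(1, 0.05, 0.05), (10, 0.05, 0.005)])
    def test_small_cases(self, n, alpha, expected):
        assert bonferroni_threshold(n, alpha) == pytest.approx(expected)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0, 0.05)
        with pytest.raises(ValueError):
            bonferroni_threshold(10, 1.5)


def _cohort(**kw):
    defaults = dict(n_pedigrees=10, pedigree_size=12, n_snps=3, seed=99)
    defaults.update(kw)
    return simulate_cohort(SimConfig(**defaults))


class TestRunScan:
    def test_minimal_scan_populates_all_fields(self):
        c = _cohort(n_snps=1)
        rows = list(run_scan(c.genotypes, c.subjects, ["env_medicine"],
                             ["dbp_mean"], schemes=("global",), B=49, seed=1))
        assert len(rows) == 1
        r = rows[0]
        assert r.flag in ("", "low_mac")
        assert r.scores is not None and r.n_used == 120
        assert 1 / 50 <= r.p_perm["global"] <= 1.0
        assert 0 < r.p_lrm <= 1.0

    def test_row_count_is_snps_times_envs_times_outcomes(self):
        c = _cohort()
        rows = list(run_scan(c.genotypes, c.subjects,
                             ["env_medicine", "env_gender"],
                             ["dbp_mean", "sbp_mean"],
                             schemes=("global",), B=19, seed=1))
        assert len(rows) == 3 * 2 * 2

    def test_lrm_and_pbi_share_complete_case_subjects(self):
        c = _cohort(n_snps=1)
        sub = c.subjects.copy()
        sub.loc[3, "dbp_mean"] = np.nan
        sub.loc[5, "env_medicine"] = np.nan
        geno = c.genotypes
        geno.dosages[0, 7] = np.nan
        rows = list(run_scan(geno, sub, ["env_medicine"], ["dbp_mean"],
                             schemes=("global",), B=19, seed=1))
        assert rows[0].n_used == 117
        assert rows[0].scores.n_used == 117
        assert rows[0].p_lrm is not None  # fitted on the same 117 subjects

    def test_misaligned_subject_ids_hard_error(self):
        c = _cohort(n_snps=1)
        sub = c.subjects.copy()
        sub.loc[0, "subject_id"] = "STRANGER"
        with pytest.raises(ValueError, match="STRANGER|S00000"):
            list(run_scan(c.genotypes, sub, ["env_medicine"], ["dbp_mean"],
                          schemes=("global",), B=9, seed=1))

    def test_subject_order_is_matched_by_id_not_position(self):
        c = _cohort(n_snps=2)
        kw = dict(schemes=("global",), B=49, seed=5)
        base = list(run_scan(c.genotypes, c.subjects, ["env_medicine"],
                             ["dbp_mean"], **kw))
        shuffled = c.subjects.sample(frac=1.0, random_state=0).reset_index(drop=True)
        perm = list(run_scan(c.genotypes, shuffled, ["env_medicine"],
                             ["dbp_mean"], **kw))
        for a, b in zip(base, perm):
            assert a.p_perm == b.p_perm
            assert a.scores.i_gxe == pytest.approx(b.scores.i_gxe, rel=1e-12)

    def test_degenerate_triples_are_flagged_skips(self):
        c = _cohort(n_snps=2)
        sub = c.subjects.copy()
        sub["env_const"] = 1.0
        geno = c.genotypes
        geno.dosages[1, :] = 0.0  # monomorphic SNP
        rows = list(run_scan(geno, sub, ["env_const"], ["dbp_mean"],
                             schemes=("global",), B=9, seed=1))
        assert all(r.flag == "skip_single_level" for r in rows)
        assert all(r.p_perm == {} and r.p_lrm is None for r in rows)

    def test_simulated_signal_snp_ranks_first_among_nulls(self):
        c = simulate_cohort(SimConfig(model="crossing_gxe", n_snps=101, seed=17))
        rows = list(run_scan(c.genotypes, c.subjects, ["env_medicine"],
                             ["dbp_mean"], schemes=(), B=1, seed=1))
        i_gxe = np.array([r.scores.i_gxe for r in rows])
        assert int(np.argmax(i_gxe)) == c.causal_index == 0

    def test_rerun_same_seed_byte_identical(self):
        c = _cohort()
        out = []
        for _ in range(2):
            buf = _io.StringIO()
            write_results(
                run_scan(c.genotypes, c.subjects, ["env_medicine"], ["dbp_mean"],
                         schemes=("global", "local"), B=99, seed=3),
                buf, ("global", "local"),
            )
            out.append(buf.getvalue())
        assert out[0] == out[1]
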