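"""Genome scan over SNP x environment x outcome combinations.

For each combination the partition-based interaction score I_GxE is
computed on the complete-case subjects, permutation p-values are drawn
under the requested schemes, and the linear-regression comparator

    y = b0 + b1*G + b2*E + b3*G*E + eps

is fitted by OLS on the *same* subjects, reporting the two-sided t-test
p-value for the interaction coefficient b3.  The environment enters the
regression as its discretized numeric level by default (so both methods
see identical predictors); a raw continuous covariate can be substituted
per factor.  The OLS fit deliberately ignores family structure — it is
the plain linear-model baseline the partition test is compared against —
while the permutation schemes are where relatedness is handled.

Results stream one record at a time, so memory stays proportional to
the cohort, not the SNP panel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .core import DegenerateSampleError, GxEScores, gxe_scores
from .covariates import _flip_to_minor
from .io import GenotypeMatrix
from .permutation import PermutationPlan, derive_seed, gxe_permutation_pvalue

logger = logging.getLogger(__name__)

#: a test is skipped (flagged null row) below this complete-case count
MIN_N_USED = 10
#: minor-allele-count floor below which permutation p-values get noisy
MIN_MAC = 5


@dataclass(frozen=True, eq=False)
class LRMFit:
    """OLS fit of the linear interaction model for one test."""

    beta: np.ndarray  # (b0, b1, b2, b3)
    se3: float
    p3: float


class RankDeficientDesignError(ValueError):
    """Design matrix [1, g, e, g*e] is not full column rank."""


def lrm_interaction_test(y, g, e) -> LRMFit:
    """Two-sided t-test for the G*E coefficient in the linear model.

    ``g`` is the 0/1/2 minor-allele dosage and ``e`` the environment
    treated as a numeric score.  Requires >= 5 complete cases and a
    full-rank design; raises :class:`RankDeficientDesignError` otherwise
    (the scan converts this into a flagged skip).
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    e = np.asarray(e, dtype=float)
    if not (y.shape == g.shape == e.shape) or y.ndim != 1:
        raise ValueError("y, g and e must be parallel 1-d vectors")
    if np.isnan(y).any() or np.isnan(g).any() or np.isnan(e).any():
        raise ValueError("missing values present; filter complete cases first")
    if y.size < 5:
        raise ValueError(f"need >= 5 subjects for the 4-parameter fit, got {y.size}")
    X = np.column_stack([np.ones_like(g), g, e, g * e])
    if np.linalg.matrix_rank(X) < 4:
        raise RankDeficientDesignError("design matrix [1, g, e, g*e] is rank-deficient")
    fit = sm.OLS(y, X).fit()
    return LRMFit(beta=np.asarray(fit.params), se3=float(fit.bse[3]),
                  p3=float(fit.pvalues[3]))


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """Per-test significance level controlling the familywise error rate."""
    if n_tests < 1:
        raise ValueError(f"n_tests must be >= 1, got {n_tests}")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    return alpha / n_tests


@dataclass(eq=False)
class ScanResult:
    """Scores and p-values for one (SNP, environment, outcome) test."""

    snp_id: str
    chrom: str
    pos: int
    env: str
    outcome: str
    n_used: int
    scores: GxEScores | None = None
    p_perm: dict = field(default_factory=dict)
    p_lrm: float | None = None
    flag: str = ""


def _align(genotypes: GenotypeMatrix, subjects: pd.DataFrame) -> pd.DataFrame:
    ids = subjects["subject_id"].astype(str)
    if ids.duplicated().any():
        raise ValueError("duplicate subject_id rows in subject table")
    samples = [str(s) for s in genotypes.samples]
    missing_pheno = sorted(set(samples) - set(ids))
    missing_geno = sorted(set(ids) - set(samples))
    if missing_pheno or missing_geno:
        raise ValueError(
            "subject ids do not align between genotypes and phenotypes; "
            f"no phenotype for {missing_pheno[:5]}, no genotype for {missing_geno[:5]}"
        )
    return subjects.set_index(ids).loc[samples].reset_index(drop=True)


def run_scan(
    genotypes: GenotypeMatrix,
    subjects: pd.DataFrame,
    envs: Sequence[str],
    outcomes: Sequence[str],
    schemes: Sequence[str] = ("global", "local", "residual"),
    B: int = 999,
    seed: int = 0,
    adaptive: bool = False,
    lrm_raw_env: dict[str, str] | None = None,
) -> Iterator[ScanResult]:
    """Yield one :class:`ScanResult` per (SNP, environment, outcome).

    ``envs`` and ``outcomes`` name columns of ``subjects`` holding the
    discretized environment levels and the summarized outcomes.
    Subject alignment between ``genotypes.samples`` and
    ``subjects.subject_id`` is by id, never by position; mismatched id
    sets are a hard error.  Each test draws its permutations from an
    RNG stream derived from (seed, SNP index, environment, outcome,
    scheme), so results are reproducible under any execution order.

    Per-test degeneracies (too few complete cases, single-level factors,
    constant outcome, rank-deficient regression design) become flagged
    rows with ``NA`` p-values; the scan continues.
    """
    subjects = _align(genotypes, subjects)
    for name in list(envs) + list(outcomes):
        if name not in subjects.columns:
            raise ValueError(f"column {name!r} not in subject table")
    lrm_raw_env = lrm_raw_env or {}
    peds = subjects["pedigree_id"].to_numpy()

    for s_idx in range(genotypes.n_snps):
        dose = genotypes.dosages[s_idx]
        for env in envs:
            e_all = subjects[env].to_numpy(dtype=float)
            for outcome in outcomes:
                y_all = subjects[outcome].to_numpy(dtype=float)
                yield _scan_one(
                    genotypes, s_idx, dose, env, e_all, outcome, y_all,
                    peds, subjects, schemes, B, seed, adaptive, lrm_raw_env,
                )


def _scan_one(genotypes, s_idx, dose, env, e_all, outcome, y_all, peds,
              subjects, schemes, B, seed, adaptive, lrm_raw_env) -> ScanResult:
    res = ScanResult(
        snp_id=str(genotypes.snp_ids[s_idx]), chrom=str(genotypes.chrom[s_idx]),
        pos=int(genotypes.pos[s_idx]), env=env, outcome=outcome, n_used=0,
    )
    mask = ~(np.isnan(y_all) | np.isnan(dose) | np.isnan(e_all))
    y, e = y_all[mask], e_all[mask]
    g = _flip_to_minor(dose[mask])  # minor allele defined in analyzed subjects
    ped = peds[mask]
    res.n_used = int(mask.sum())

    flags = []
    if res.n_used < MIN_N_USED:
        res.flag = "skip_small_n"
        return res
    if np.unique(g).size < 2 or np.unique(e).size < 2:
        res.flag = "skip_single_level"
        return res
    if np.var(y, ddof=1) <= 0.0:
        res.flag = "skip_constant_outcome"
        return res
    mac = min(g.sum(), (2.0 - g).sum())
    if mac < MIN_MAC:
        flags.append("low_mac")

    try:
        res.scores = gxe_scores(y, g, e)
    except DegenerateSampleError as exc:  # pragma: no cover - guarded above
        res.flag = f"skip_degenerate:{exc}"
        return res

    g_codes = g.astype(int)
    e_codes, _ = pd.factorize(e, sort=True)
    for scheme in schemes:
        plan = PermutationPlan(
            scheme=scheme, B=B, adaptive=adaptive,
            seed=derive_seed(seed, s_idx, env, outcome, scheme),
        )
        res.p_perm[scheme] = gxe_permutation_pvalue(
            y, g_codes, e_codes, res.scores.i_gxe, pedigree_of=ped, plan=plan,
        )

    e_lrm = e
    if env in lrm_raw_env:
        e_lrm = subjects[lrm_raw_env[env]].to_numpy(dtype=float)[mask]
    try:
        res.p_lrm = lrm_interaction_test(y, g, e_lrm).p3
    except (RankDeficientDesignError, ValueError) as exc:
        flags.append("lrm_rank_deficient")
        logger.warning("LRM skipped for %s/%s/%s: %s", res.snp_id, env, outcome, exc)
    res.flag = ";".join(flags)
    return res
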