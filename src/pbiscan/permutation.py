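"""Permutation null distributions for family-structured phenotypes.

Three phenotype-permutation strategies are provided for samples whose
subjects fall into pedigrees (families sharing a phenotype-correlating
random effect):

* **global** -- shuffle phenotypes over all subjects; valid when
  phenotypes are exchangeable across the whole sample.
* **local** -- shuffle phenotypes within each pedigree only; conditions
  on the pedigree phenotype profile and so remains valid when pedigrees
  differ in mean.
* **residual** -- centre each subject's phenotype on its pedigree mean,
  shuffle the residuals e_ij = y_ij - ybar_i. over all subjects, and
  reconstruct y*_ij = ybar_i. + e*_ij; assumes the residuals share one
  distribution across pedigrees.

Genotype and environment labels are never permuted: the null being
sampled is "the phenotype carries no information about the partition".

p-values use the add-one estimator p = (1 + #{stat_b >= observed}) /
(1 + B), which is never anti-conservative and never exactly zero; ties
with the observed statistic count as exceedances.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .core import gxe_interaction_scores_batch

logger = logging.getLogger(__name__)

SCHEMES = ("global", "local", "residual")


@dataclass(frozen=True, eq=False)
class PedigreePhenotypes:
    """Phenotypes grouped by pedigree, with per-pedigree means and residuals.

    ``fitted`` holds each subject's pedigree mean ybar_i. and
    ``residuals`` the within-pedigree deviations e_ij = y_ij - ybar_i.,
    which sum to zero inside every pedigree.
    """

    y: np.ndarray
    pedigree_of: np.ndarray
    ped_ids: np.ndarray
    ped_means: np.ndarray
    fitted: np.ndarray
    residuals: np.ndarray
    groups: list  # list of index arrays, one per pedigree

    @classmethod
    def from_arrays(cls, y, pedigree_of) -> "PedigreePhenotypes":
        y = np.asarray(y, dtype=float)
        pedigree_of = np.asarray(pedigree_of)
        if y.shape != pedigree_of.shape or y.ndim != 1:
            raise ValueError("y and pedigree_of must be parallel 1-d vectors")
        codes, ped_ids = pd.factorize(pedigree_of, sort=True)
        k = len(ped_ids)
        counts = np.bincount(codes, minlength=k)
        ped_means = np.bincount(codes, weights=y, minlength=k) / counts
        fitted = ped_means[codes]
        groups = [np.flatnonzero(codes == i) for i in range(k)]
        return cls(
            y=y, pedigree_of=pedigree_of, ped_ids=np.asarray(ped_ids),
            ped_means=ped_means, fitted=fitted, residuals=y - fitted,
            groups=groups,
        )


@dataclass(frozen=True)
class PermutationPlan:
    """How to sample the permutation null for one test.

    ``adaptive`` stops drawing once ``adaptive_min_exceed`` permuted
    statistics have reached the observed value, trading p-value
    resolution for speed on clearly null tests; off by default.
    """

    scheme: str = "global"
    B: int = 999
    seed: int | np.random.SeedSequence = 0
    adaptive: bool = False
    adaptive_min_exceed: int = 50

    def __post_init__(self):
        if self.scheme not in SCHEMES:
            raise ValueError(f"scheme must be one of {SCHEMES}, got {self.scheme!r}")
        if self.B < 1:
            raise ValueError("B must be >= 1")


def _pedigree_groups(pedigree_of) -> list:
    codes, _ = pd.factorize(np.asarray(pedigree_of), sort=True)
    return [np.flatnonzero(codes == i) for i in range(codes.max() + 1)]


def permute_global(y, rng: np.random.Generator) -> np.ndarray:
    """Uniformly random rearrangement of the whole phenotype vector."""
    y = np.asarray(y, dtype=float)
    return y[rng.permutation(y.size)]


def _local_shuffle(y: np.ndarray, groups: Sequence[np.ndarray],
                   rng: np.random.Generator) -> np.ndarray:
    out = y.copy()
    for idx in groups:
        if idx.size > 1:
            out[idx] = y[idx[rng.permutation(idx.size)]]
    return out


def permute_local(y, pedigree_of, rng: np.random.Generator) -> np.ndarray:
    """Shuffle phenotypes within each pedigree; values never cross pedigrees."""
    y = np.asarray(y, dtype=float)
    return _local_shuffle(y, _pedigree_groups(pedigree_of), rng)


def _residual_shuffle(fitted: np.ndarray, residuals: np.ndarray,
                      rng: np.random.Generator) -> np.ndarray:
    return fitted + residuals[rng.permutation(residuals.size)]


def permute_residual(y, pedigree_of, rng: np.random.Generator) -> np.ndarray:
    """Shuffle pedigree-mean-centred residuals globally and reconstruct."""
    ped = PedigreePhenotypes.from_arrays(y, pedigree_of)
    return _residual_shuffle(ped.fitted, ped.residuals, rng)


def _draw_fn(scheme: str, y: np.ndarray, pedigree_of) -> Callable:
    """Bind a scheme to a zero-argument-per-draw kernel taking only rng."""
    if scheme == "global":
        return lambda rng: y[rng.permutation(y.size)]
    if pedigree_of is None:
        raise ValueError(f"{scheme} permutation requires pedigree ids")
    if scheme == "local":
        groups = _pedigree_groups(pedigree_of)
        return lambda rng: _local_shuffle(y, groups, rng)
    if scheme == "residual":
        ped = PedigreePhenotypes.from_arrays(y, pedigree_of)
        return lambda rng: _residual_shuffle(ped.fitted, ped.residuals, rng)
    raise ValueError(f"unknown scheme {scheme!r}")


def permutation_pvalue(
    observed: float,
    stat_fn: Callable[[np.ndarray], float],
    y,
    pedigree_of=None,
    plan: PermutationPlan = PermutationPlan(),
) -> float:
    """Permutation p-value of an observed statistic.

    ``stat_fn`` recomputes the statistic on a permuted phenotype vector
    with all other inputs held fixed.  A draw on which ``stat_fn``
    raises is retried once and otherwise counted as an exceedance
    (conservative), with a logged warning.

    Returns (1 + r) / (1 + B) where r counts permuted statistics >= the
    observed one; always in [1/(B+1), 1].
    """
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(plan.seed)
    draw = _draw_fn(plan.scheme, y, pedigree_of)
    r = 0
    b_done = 0
    for _ in range(plan.B):
        y_b = draw(rng)
        try:
            stat = stat_fn(y_b)
        except Exception:
            try:
                stat = stat_fn(draw(rng))
            except Exception as exc:  # count as exceedance: conservative
                logger.warning(
                    "statistic failed on permuted draw (%s); counting as >= observed",
                    exc,
                )
                stat = np.inf
        if stat >= observed:
            r += 1
        b_done += 1
        if plan.adaptive and r >= plan.adaptive_min_exceed:
            break
    return (1 + r) / (1 + b_done)


def gxe_permutation_pvalue(
    y: np.ndarray,
    g_codes: np.ndarray,
    e_codes: np.ndarray,
    observed: float,
    pedigree_of=None,
    plan: PermutationPlan = PermutationPlan(),
    chunk_rows: int = 512,
) -> float:
    """Fast permutation p-value for the I_GxE statistic.

    Draw-for-draw equivalent to :func:`permutation_pvalue` with
    ``stat_fn`` recomputing I_GxE (same RNG stream, same add-one/tie
    conventions) but evaluates the statistic on blocks of permuted
    phenotype rows with vectorised group sums.  With ``adaptive`` set,
    stops at the end of the first block satisfying the exceedance rule.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    rng = np.random.default_rng(plan.seed)
    draw = _draw_fn(plan.scheme, y, pedigree_of)
    r = 0
    b_done = 0
    remaining = plan.B
    block = np.empty((min(chunk_rows, remaining), n))
    while remaining > 0:
        m = min(chunk_rows, remaining)
        for i in range(m):
            block[i] = draw(rng)
        stats = gxe_interaction_scores_batch(block[:m], g_codes, e_codes)
        r += int(np.count_nonzero(stats >= observed))
        b_done += m
        remaining -= m
        if plan.adaptive and r >= plan.adaptive_min_exceed:
            break
    return (1 + r) / (1 + b_done)


def derive_seed(base_seed: int, *keys) -> np.random.SeedSequence:
    """Deterministic per-test RNG stream from a base seed and context keys.

    String keys (SNP id, environment name, scheme) are hashed with
    CRC-32 so the stream is stable across platforms, interpreter
    sessions and any degree of parallel scan execution.
    """
    entropy = [int(base_seed)]
    for k in keys:
        if isinstance(k, (int, np.integer)):
            entropy.append(int(k))
        else:
            entropy.append(zlib.crc32(str(k).encode("utf-8")))
    return np.random.SeedSequence(entropy)
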