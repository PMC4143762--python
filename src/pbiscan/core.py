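"""Partition-based association scores for quantitative traits.

The central quantity is a nonparametric association measure between a
quantitative outcome ``y`` and a categorical partition of the sample:

    I = sum_i (n_i / n) * (ybar_i - ybar)^2 / (s_y^2 / n_i)

summed over the non-empty partition cells, where ``n_i`` and ``ybar_i``
are the size and outcome mean of cell *i* and ``ybar``, ``s_y^2`` are
the grand mean and variance of the outcome.  The score is zero when no
cell mean deviates from the grand mean, grows with both cell occupancy
and mean separation, and is invariant under affine rescaling of ``y``
and under any relabelling of the cells.

For a genotype factor G (minor-allele dosage 0/1/2) crossed with a
discretized environmental factor E, three scores are computed: the
total score ``I_T`` over the joint G-by-E cells, and the marginal
scores ``I_G`` and ``I_E``.  The gene-environment interaction score is

    I_GxE = I_T - max(I_G, I_E)

which is large and positive when the joint partition explains outcome
structure that neither margin alone does.  ``I_GxE`` may be negative
(e.g. under an additive model); it is reported as-is so the permutation
reference distribution is honest.  Significance is assessed exclusively
by permutation (see :mod:`pbiscan.permutation`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: ddof used for the outcome variance s_y^2 in every score.  The sample
#: (n-1) convention is used; switching to the maximum-likelihood (n)
#: convention rescales every score by the constant (n-1)/n and leaves
#: permutation p-values unchanged, since the same vector enters the
#: observed and every permuted statistic.
VARIANCE_DDOF: int = 1


class DegenerateSampleError(ValueError):
    """Raised when a sample cannot be scored (n < 2 or constant outcome)."""


@dataclass(frozen=True, eq=False)
class PartitionedSample:
    """A quantitative outcome with a categorical partition of its subjects.

    Attributes
    ----------
    y : ndarray
        Outcome values (trait units), complete cases only.
    codes : ndarray of int
        Partition cell per subject as integer codes ``0..k-1``.
    levels : ndarray
        Original cell identities; ``levels[codes[j]]`` is subject j's label.
    n : int
        Total number of subjects.
    n_i : ndarray of int
        Subjects per cell, parallel to ``levels``.
    y_bar : float
        Grand mean of ``y``.
    s2 : float
        Variance of ``y`` with ``ddof=VARIANCE_DDOF`` (trait units squared).
    """

    y: np.ndarray
    codes: np.ndarray
    levels: np.ndarray
    n: int
    n_i: np.ndarray
    y_bar: float
    s2: float

    @classmethod
    def from_arrays(cls, y, labels) -> "PartitionedSample":
        """Build and validate a sample from parallel outcome/label vectors.

        Raises
        ------
        DegenerateSampleError
            If fewer than two subjects remain or the outcome is constant.
        ValueError
            On length mismatch or missing values (callers filter complete
            cases first; see :func:`gxe_scores`).
        """
        y = np.asarray(y, dtype=float)
        labels = np.asarray(labels)
        if y.ndim != 1 or labels.shape != y.shape:
            raise ValueError(
                f"y and labels must be parallel 1-d vectors, got shapes "
                f"{y.shape} and {labels.shape}"
            )
        if y.size == 0:
            raise DegenerateSampleError("empty sample")
        if np.isnan(y).any() or pd.isna(labels).any():
            raise ValueError("missing values present; filter complete cases first")
        if y.size < 2:
            raise DegenerateSampleError("need at least 2 subjects to score")
        codes, levels = pd.factorize(labels, sort=True)
        y_bar = float(y.mean())
        s2 = float(y.var(ddof=VARIANCE_DDOF))
        if not s2 > 0.0:
            raise DegenerateSampleError("constant outcome: zero variance")
        n_i = np.bincount(codes, minlength=len(levels))
        return cls(
            y=y, codes=codes, levels=np.asarray(levels), n=int(y.size),
            n_i=n_i, y_bar=y_bar, s2=s2,
        )


def _score_from_codes(
    y: np.ndarray, codes: np.ndarray, k: int, n: int, y_bar: float, s2: float
) -> float:
    # I = sum_i n_i^2 (ybar_i - ybar)^2 / (n s2); empty cells contribute 0
    counts = np.bincount(codes, minlength=k)
    sums = np.bincount(codes, weights=y, minlength=k)
    nz = counts > 0
    means = sums[nz] / counts[nz]
    return float(np.sum(counts[nz] ** 2 * (means - y_bar) ** 2) / (n * s2))


def partition_score(sample: PartitionedSample) -> float:
    """Association score between the outcome and the partition.

    Returns the nonnegative, affine-invariant statistic
    ``sum_i (n_i/n)(ybar_i - ybar)^2 / (s2/n_i)`` over non-empty cells.
    """
    return _score_from_codes(
        sample.y, sample.codes, len(sample.levels), sample.n, sample.y_bar, sample.s2
    )


@dataclass(frozen=True, eq=False)
class GxEScores:
    """Joint, marginal and interaction scores for one SNP-environment pair.

    ``cell_counts[i, j]`` is the number of subjects with genotype level
    ``g_levels[i]`` and environment level ``e_levels[j]``; only levels
    observed in the analyzed (complete-case) subjects appear.
    """

    i_t: float
    i_g: float
    i_e: float
    i_gxe: float
    cell_counts: np.ndarray
    g_levels: np.ndarray
    e_levels: np.ndarray
    n_used: int


def _complete_case_mask(y: np.ndarray, g, e) -> np.ndarray:
    return ~(np.isnan(y) | pd.isna(np.asarray(g)) | pd.isna(np.asarray(e)))


def gxe_scores(y, g_labels, e_labels) -> GxEScores:
    """Score a genotype-environment pair against a quantitative outcome.

    Subjects missing any of the three values are dropped (complete-case
    per pair).  Genotype and environment levels absent from the analyzed
    subjects contribute nothing: the nominal 3x3 genotype-by-environment
    grid generalizes to however many levels are observed, so binary
    factors and monomorphic sites are handled uniformly.

    Raises
    ------
    DegenerateSampleError
        If fewer than two complete cases remain or the outcome is constant.
    """
    y = np.asarray(y, dtype=float)
    g_labels = np.asarray(g_labels)
    e_labels = np.asarray(e_labels)
    if not (y.shape == g_labels.shape == e_labels.shape) or y.ndim != 1:
        raise ValueError("y, g_labels and e_labels must be parallel 1-d vectors")
    mask = _complete_case_mask(y, g_labels, e_labels)
    y, g_labels, e_labels = y[mask], g_labels[mask], e_labels[mask]
    n = int(y.size)
    if n < 2:
        raise DegenerateSampleError(f"only {n} complete case(s); need at least 2")
    y_bar = float(y.mean())
    s2 = float(y.var(ddof=VARIANCE_DDOF))
    if not s2 > 0.0:
        raise DegenerateSampleError("constant outcome: zero variance")
    g_codes, g_levels = pd.factorize(g_labels, sort=True)
    e_codes, e_levels = pd.factorize(e_labels, sort=True)
    kg, ke = len(g_levels), len(e_levels)
    joint = g_codes * ke + e_codes
    i_g = _score_from_codes(y, g_codes, kg, n, y_bar, s2)
    i_e = _score_from_codes(y, e_codes, ke, n, y_bar, s2)
    i_t = _score_from_codes(y, joint, kg * ke, n, y_bar, s2)
    cell_counts = np.bincount(joint, minlength=kg * ke).reshape(kg, ke)
    return GxEScores(
        i_t=i_t, i_g=i_g, i_e=i_e, i_gxe=i_t - max(i_g, i_e),
        cell_counts=cell_counts, g_levels=np.asarray(g_levels),
        e_levels=np.asarray(e_levels), n_used=n,
    )


def _onehot(codes: np.ndarray, k: int) -> np.ndarray:
    """Dense n-by-k indicator matrix for batched group sums."""
    m = np.zeros((codes.size, k))
    m[np.arange(codes.size), codes] = 1.0
    return m


def gxe_interaction_scores_batch(
    Y: np.ndarray, g_codes: np.ndarray, e_codes: np.ndarray
) -> np.ndarray:
    """I_GxE for every row of a (B, n) matrix of outcome vectors.

    Labels are held fixed across rows; the grand mean and variance are
    recomputed per row (residual permutation changes the value multiset).
    Used by the permutation fast path; must agree with :func:`gxe_scores`
    row by row.
    """
    Y = np.asarray(Y, dtype=float)
    B, n = Y.shape
    kg = int(g_codes.max()) + 1
    ke = int(e_codes.max()) + 1
    joint = g_codes * ke + e_codes
    y_bar = Y.mean(axis=1)
    s2 = Y.var(axis=1, ddof=VARIANCE_DDOF)
    out = np.empty(B)

    def scores_for(codes: np.ndarray, k: int) -> np.ndarray:
        counts = np.bincount(codes, minlength=k)
        nz = counts > 0
        sums = Y @ _onehot(codes, k)[:, nz]
        means = sums / counts[nz]
        dev = means - y_bar[:, None]
        return (counts[nz] ** 2 * dev**2).sum(axis=1)

    i_g = scores_for(g_codes, kg)
    i_e = scores_for(e_codes, ke)
    i_t = scores_for(joint, kg * ke)
    out = (i_t - np.maximum(i_g, i_e)) / (n * s2)
    return out
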