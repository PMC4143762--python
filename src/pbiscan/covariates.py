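"""Longitudinal covariate summarization and discretization.

Cohorts with repeated visits (up to four in the motivating blood-pressure
data) are reduced to one row per subject: age and the blood-pressure
outcomes are averaged over available visits, binary per-visit indicators
(current smoking, antihypertensive medication use) are summed into
counts.  The summarized values are then discretized into the categorical
levels the partition score consumes:

* continuous summaries (age) -> empirical tertiles, levels {0, 1, 2};
* visit counts (smoking, medicine) -> 0 -> 0, 1 -> 1, >=2 -> 2;
* binary factors (gender) -> passed through as two levels {0, 1}.

Genotypes are coded as minor-allele dosage 0/1/2, the minor allele being
the less frequent allele *in the analyzed sample* (reference allele wins
a 50/50 tie).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: columns of the per-subject table produced by :func:`build_subject_table`
SUBJECT_COLUMNS = [
    "subject_id", "pedigree_id", "gender", "age_mean", "smoke_sum",
    "med_sum", "sbp_mean", "dbp_mean",
    "env_age", "env_gender", "env_smoke", "env_medicine",
]


def summarize_longitudinal(values, method: str) -> float:
    """Reduce one subject's per-visit values to a single number.

    ``method='mean'`` averages over non-missing visits (age, SBP, DBP);
    ``method='sum'`` totals them (smoking, medicine counts).  All visits
    missing yields NaN, which later propagates to complete-case
    filtering rather than raising.
    """
    values = np.asarray(values, dtype=float)
    ok = ~np.isnan(values)
    if not ok.any():
        return float("nan")
    if method == "mean":
        return float(values[ok].mean())
    if method == "sum":
        return float(values[ok].sum())
    raise ValueError(f"method must be 'mean' or 'sum', got {method!r}")


def discretize_env(values, scheme: str, factor: str = "factor") -> np.ndarray:
    """Discretize per-subject summarized values into partition levels.

    tertile
        Empirical 1/3 and 2/3 quantiles (linear interpolation of order
        statistics) split subjects into levels 0/1/2; assignment is
        right-closed (value <= lower break -> 0, <= upper break -> 1,
        else 2).  Requires at least 3 distinct non-missing values.
    count_recode
        0 -> 0, 1 -> 1, anything >= 2 -> 2 (idempotent).
    binary
        Two observed levels mapped to 0/1 in sorted order.

    Missing values stay missing (NaN) in the output.
    """
    values = np.asarray(values, dtype=float)
    out = np.full(values.shape, np.nan)
    ok = ~np.isnan(values)
    if scheme == "tertile":
        distinct = np.unique(values[ok])
        if distinct.size < 3:
            raise ValueError(
                f"tertile discretization of {factor!r} needs >=3 distinct "
                f"values, got {distinct.size}"
            )
        lo, hi = np.quantile(values[ok], [1 / 3, 2 / 3])
        out[ok] = np.where(values[ok] <= lo, 0.0, np.where(values[ok] <= hi, 1.0, 2.0))
    elif scheme == "count_recode":
        out[ok] = np.minimum(values[ok], 2.0)
    elif scheme == "binary":
        distinct = np.unique(values[ok])
        if distinct.size > 2:
            raise ValueError(
                f"binary discretization of {factor!r} saw {distinct.size} levels"
            )
        out[ok] = np.searchsorted(distinct, values[ok]).astype(float)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    return out


class MultiallelicSiteError(ValueError):
    """Raised for genotype calls involving more than two alleles."""


_MISSING_CALLS = {"", "NA", ".", "./.", ".|."}


def code_genotypes(calls) -> np.ndarray:
    """Minor-allele dosage 0/1/2 per subject for one biallelic SNP.

    Accepts either numeric alt-allele dosages (0/1/2, NaN missing) or
    allele-pair strings such as ``"AA"``, ``"Aa"``, ``"A/a"``.  The
    minor allele is the less frequent allele among the non-missing
    calls; dosages are flipped if needed so 2 always counts minor-allele
    copies.  At an exact 50/50 frequency tie the first (reference)
    allele is treated as major.

    Raises
    ------
    MultiallelicSiteError
        If more than two alleles appear; callers skip the site with a
        warning.
    """
    calls = np.asarray(calls)
    if calls.dtype.kind in "fiu":
        dose = np.asarray(calls, dtype=float)
        bad = ~np.isin(dose[~np.isnan(dose)], [0.0, 1.0, 2.0])
        if bad.any():
            raise ValueError("numeric genotype dosages must be 0, 1, 2 or missing")
        return _flip_to_minor(dose)
    # string allele pairs
    dose = np.full(calls.shape, np.nan)
    alleles: list[str] = []
    pairs = []
    for s in calls:
        s = "" if pd.isna(s) else str(s).strip()
        if s in _MISSING_CALLS:
            pairs.append(None)
            continue
        pair = tuple(s.replace("|", "/").split("/")) if "/" in s or "|" in s else tuple(s)
        if len(pair) != 2 or "." in pair:
            pairs.append(None)
            continue
        for a in pair:
            if a not in alleles:
                alleles.append(a)
        pairs.append(pair)
    if len(alleles) > 2:
        raise MultiallelicSiteError(f"site has {len(alleles)} alleles: {alleles}")
    if not alleles:
        return dose
    ref = alleles[0]
    for i, pair in enumerate(pairs):
        if pair is not None:
            dose[i] = sum(a != ref for a in pair)
    return _flip_to_minor(dose)


def _flip_to_minor(dose: np.ndarray) -> np.ndarray:
    """Flip 0<->2 if the counted allele is the majority allele (ties keep)."""
    ok = ~np.isnan(dose)
    if not ok.any():
        return dose
    alt_freq = dose[ok].mean() / 2.0
    if alt_freq > 0.5:
        out = dose.copy()
        out[ok] = 2.0 - out[ok]
        return out
    return dose


REQUIRED_LONG_COLUMNS = [
    "subject_id", "pedigree_id", "visit", "age", "smoke", "medicine",
    "gender", "SBP", "DBP",
]


def build_subject_table(long_df: pd.DataFrame) -> pd.DataFrame:
    """Collapse a long-format visit table into one row per subject.

    Produces the summarized covariates (age_mean, smoke_sum, med_sum,
    sbp_mean, dbp_mean) and the discretized environment levels
    (env_age tertiles, env_smoke / env_medicine count recodes,
    env_gender binary).  A factor whose cohort-wide discretization is
    impossible (e.g. constant age) yields an all-missing level column
    with a logged warning rather than failing the whole table.
    """
    missing = [c for c in REQUIRED_LONG_COLUMNS if c not in long_df.columns]
    if missing:
        raise ValueError(f"phenotype table missing required column(s): {missing}")
    grouped = long_df.groupby("subject_id", sort=True)
    ped = grouped["pedigree_id"].agg(lambda s: s.iloc[0])
    gender = grouped["gender"].agg(lambda s: s.dropna().iloc[0] if s.notna().any() else np.nan)
    rows = pd.DataFrame({
        "subject_id": ped.index,
        "pedigree_id": ped.to_numpy(),
        "gender": gender.to_numpy(dtype=float),
        "age_mean": grouped["age"].agg(summarize_longitudinal, method="mean").to_numpy(),
        "smoke_sum": grouped["smoke"].agg(summarize_longitudinal, method="sum").to_numpy(),
        "med_sum": grouped["medicine"].agg(summarize_longitudinal, method="sum").to_numpy(),
        "sbp_mean": grouped["SBP"].agg(summarize_longitudinal, method="mean").to_numpy(),
        "dbp_mean": grouped["DBP"].agg(summarize_longitudinal, method="mean").to_numpy(),
    }).reset_index(drop=True)

    for col, src, scheme in [
        ("env_age", "age_mean", "tertile"),
        ("env_gender", "gender", "binary"),
        ("env_smoke", "smoke_sum", "count_recode"),
        ("env_medicine", "med_sum", "count_recode"),
    ]:
        try:
            rows[col] = discretize_env(rows[src].to_numpy(), scheme, factor=src)
        except ValueError as exc:
            logger.warning("cannot discretize %s: %s", src, exc)
            rows[col] = np.nan
    return rows
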