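"""Synthetic family cohorts for validating the interaction scan.

Cohorts mimic the structure the test is designed for: multiple
pedigrees whose members share a normal random intercept (sigma_fam),
Hardy-Weinberg genotypes at a configurable minor-allele frequency,
a three-level environmental factor, and a quantitative outcome built
from one of five models:

* ``null`` -- intercept + family effect + noise only;
* ``marginal_g`` -- adds a linear genotype effect beta_g * G;
* ``additive`` -- adds beta_g * G + beta_e * E;
* ``linear_gxe`` -- additive plus a product interaction
  beta_gxe * (G - E[G]) * (E - E[E]); the centring makes beta_g and
  beta_e the actual marginal effects, and expanding the product shows
  this is exactly the alternative the linear-regression comparator
  models (a plain G*E term with shifted marginal coefficients);
* ``crossing_gxe`` -- a 3x3 cell-mean table whose environment profile
  is non-monotone and runs in opposite directions for minor-allele
  carriers versus non-carriers, with zero marginal genotype and
  environment contrasts in expectation: a pure interaction that a
  linear G*E product term cannot represent.

Two optional clustering knobs, both 0 by default, let the cohort
violate whole-sample exchangeability the way real families do:
``fst`` draws a per-pedigree allele frequency from the Balding-Nichols
beta model so relatives share alleles, and ``env_family_corr`` gives
each subject the pedigree's shared environment level with that
probability.  With either active and sigma_fam > 0, globally permuting
phenotypes no longer reflects the null, while within-pedigree (local)
permutation does -- the motivating scenario for the family-aware
schemes.

The causal environmental factor is surfaced as the ``medicine``
covariate (visit counts 0-4 recoding back to the latent level) so the
full longitudinal summarization pipeline can run end to end; age,
smoking and gender are simulated as non-causal background covariates,
and SBP is a null outcome alongside the modelled DBP.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .covariates import discretize_env, _flip_to_minor
from .core import gxe_scores
from .io import GenotypeMatrix
from .permutation import PermutationPlan, derive_seed, gxe_permutation_pvalue
from .scan import RankDeficientDesignError, lrm_interaction_test

MODELS = ("null", "marginal_g", "additive", "linear_gxe", "crossing_gxe")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated cohort.

    Defaults give 20 pedigrees of 25 subjects (n=500), MAF 0.3, unit
    residual noise and a unit-sd family intercept -- the desk-scale
    conditions used throughout the validation experiments.
    """

    n_pedigrees: int = 20
    pedigree_size: int | tuple[int, int] = 25
    maf: float = 0.3
    n_snps: int = 1
    env_freqs: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    sigma_fam: float = 1.0
    sigma_e: float = 1.0
    fst: float = 0.0
    env_family_corr: float = 0.0
    model: str = "null"
    beta_g: float = 0.3
    beta_e: float = 0.3
    beta_gxe: float = 0.5
    crossing_delta: float = 0.5
    mu: float = 80.0
    n_visits: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}, got {self.model!r}")
        if not 0.0 < self.maf <= 0.5:
            raise ValueError(f"maf must be in (0, 0.5], got {self.maf}")
        if self.sigma_fam < 0 or self.sigma_e < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.n_pedigrees < 1 or self.n_snps < 1:
            raise ValueError("n_pedigrees and n_snps must be >= 1")
        sizes = self.pedigree_size
        lo = sizes[0] if isinstance(sizes, tuple) else sizes
        if lo < 1:
            raise ValueError("pedigree sizes must be >= 1")
        if not 0.0 <= self.fst < 1.0:
            raise ValueError(f"fst must be in [0, 1), got {self.fst}")
        if not 0.0 <= self.env_family_corr <= 1.0:
            raise ValueError("env_family_corr must be in [0, 1]")
        f = np.asarray(self.env_freqs, dtype=float)
        if f.shape != (3,) or (f < 0).any() or not np.isclose(f.sum(), 1.0):
            raise ValueError("env_freqs must be 3 nonnegative values summing to 1")
        if self.n_visits < 2 or self.n_visits > 4:
            raise ValueError("n_visits must be between 2 and 4")


@dataclass(eq=False)
class SimCohort:
    """A simulated cohort: per-subject table, genotypes, and ground truth."""

    subjects: pd.DataFrame
    genotypes: GenotypeMatrix
    causal_index: int | None
    config: SimConfig
    cell_means: np.ndarray | None = None  # crossing model's 3x3 table


def hwe_genotype_freqs(maf: float) -> np.ndarray:
    """Hardy-Weinberg genotype proportions (p^2, 2pq, q^2) for dosage 0/1/2."""
    q = maf
    p = 1.0 - q
    return np.array([p * p, 2 * p * q, q * q])


def crossing_cell_means(config: SimConfig) -> np.ndarray:
    """3x3 genotype-by-environment cell means with zero expected marginals.

    Built as delta * outer(u, v) where u (over genotype classes) is
    centred under the Hardy-Weinberg class weights and v (over
    environment levels) is the non-monotone contrast (1, -2, 1) centred
    under the environment frequencies.  Both marginal mean profiles are
    flat in expectation, so the table carries pure interaction; the
    environment profile is V-shaped for one genotype group and
    inverted-V for the other, the crossing pattern a linear product
    term cannot capture.
    """
    p = hwe_genotype_freqs(config.maf)
    f = np.asarray(config.env_freqs, dtype=float)
    u = np.array([1.0, -1.0, -1.0])
    u = u - float(p @ u)
    v = np.array([1.0, -2.0, 1.0])
    v = v - float(f @ v)
    return config.crossing_delta * np.outer(u, v)


def _pedigree_ids(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    sizes = config.pedigree_size
    if isinstance(sizes, tuple):
        lo, hi = sizes
        counts = rng.integers(lo, hi + 1, size=config.n_pedigrees)
    else:
        counts = np.full(config.n_pedigrees, int(sizes))
    return np.repeat(np.arange(config.n_pedigrees), counts)


def _draw_genotypes(config: SimConfig, ped: np.ndarray,
                    rng: np.random.Generator) -> np.ndarray:
    """(n_snps, n) minor-allele dosages; Balding-Nichols drift if fst > 0."""
    n = ped.size
    out = np.empty((config.n_snps, n))
    q, fst = config.maf, config.fst
    for s in range(config.n_snps):
        if fst > 0:
            a = q * (1 - fst) / fst
            b = (1 - q) * (1 - fst) / fst
            ped_q = rng.beta(a, b, size=config.n_pedigrees)
            out[s] = rng.binomial(2, ped_q[ped])
        else:
            out[s] = rng.binomial(2, q, size=n)
    return out


def _draw_environment(config: SimConfig, ped: np.ndarray,
                      rng: np.random.Generator) -> np.ndarray:
    n = ped.size
    e = rng.choice(3, size=n, p=np.asarray(config.env_freqs, dtype=float))
    if config.env_family_corr > 0:
        shared = rng.choice(3, size=config.n_pedigrees,
                            p=np.asarray(config.env_freqs, dtype=float))
        take = rng.random(n) < config.env_family_corr
        e[take] = shared[ped[take]]
    return e.astype(float)


def _model_terms(config: SimConfig, g: np.ndarray, e: np.ndarray,
                 cell_means: np.ndarray | None) -> np.ndarray:
    if config.model == "null":
        return np.zeros_like(g)
    if config.model == "marginal_g":
        return config.beta_g * g
    if config.model == "additive":
        return config.beta_g * g + config.beta_e * e
    if config.model == "linear_gxe":
        # the product term is centred at the population means so beta_g and
        # beta_e control the marginal effects separately from the interaction
        g0 = 2.0 * config.maf
        e0 = float(np.asarray(config.env_freqs) @ np.arange(3))
        return (config.beta_g * g + config.beta_e * e
                + config.beta_gxe * (g - g0) * (e - e0))
    # crossing_gxe
    return cell_means[g.astype(int), e.astype(int)]


def simulate_cohort(config: SimConfig) -> SimCohort:
    """Draw one cohort under the configured model; fully seed-determined."""
    rng = np.random.default_rng(derive_seed(config.seed, "cohort"))
    ped = _pedigree_ids(config, rng)
    n = ped.size
    dosages = _draw_genotypes(config, ped, rng)
    e = _draw_environment(config, ped, rng)
    fam = rng.normal(0.0, config.sigma_fam, size=config.n_pedigrees)

    cell_means = crossing_cell_means(config) if config.model == "crossing_gxe" else None
    causal = None if config.model == "null" else 0
    g_causal = dosages[0]
    dbp = (config.mu + fam[ped]
           + _model_terms(config, g_causal, e, cell_means)
           + rng.normal(0.0, config.sigma_e, size=n))
    sbp_fam = rng.normal(0.0, config.sigma_fam, size=config.n_pedigrees)
    sbp = 120.0 + sbp_fam[ped] + rng.normal(0.0, config.sigma_e, size=n)

    # background (non-causal) covariates
    age = rng.uniform(16.0, 94.0, size=n)
    smoke = rng.integers(0, config.n_visits + 1, size=n).astype(float)
    gender = rng.choice([1.0, 2.0], size=n)
    med = np.where(e < 2, e, rng.integers(2, config.n_visits + 1, size=n)).astype(float)

    subjects = pd.DataFrame({
        "subject_id": [f"S{i:05d}" for i in range(n)],
        "pedigree_id": [f"PED{p:03d}" for p in ped],
        "gender": gender,
        "age_mean": age,
        "smoke_sum": smoke,
        "med_sum": med,
        "sbp_mean": sbp,
        "dbp_mean": dbp,
        "env_age": discretize_env(age, "tertile", factor="age_mean"),
        "env_gender": discretize_env(gender, "binary", factor="gender"),
        "env_smoke": discretize_env(smoke, "count_recode"),
        "env_medicine": e,
    })
    genotypes = GenotypeMatrix(
        snp_ids=np.array([f"snp{s:05d}" for s in range(config.n_snps)], dtype=object),
        chrom=np.full(config.n_snps, "3", dtype=object),
        pos=np.arange(1, config.n_snps + 1) * 1000,
        ref=np.full(config.n_snps, "A", dtype=object),
        alt=np.full(config.n_snps, "C", dtype=object),
        dosages=dosages,
        samples=list(subjects["subject_id"]),
    )
    return SimCohort(subjects=subjects, genotypes=genotypes,
                     causal_index=causal, config=config, cell_means=cell_means)


def longitudinal_table(cohort: SimCohort) -> pd.DataFrame:
    """Expand a cohort into the long-format visit table the IO layer reads.

    Per-visit values are constructed so the summarization pipeline
    recovers the cohort exactly: visit ages and blood pressures average
    to the per-subject means, and per-visit smoking/medication
    indicators sum to the stored counts.
    """
    cfg = cohort.config
    rng = np.random.default_rng(derive_seed(cfg.seed, "visits"))
    k = cfg.n_visits
    offsets = (np.arange(k) - (k - 1) / 2.0) * 2.0  # biennial visits, zero-mean
    rows = []
    for rec in cohort.subjects.itertuples(index=False):
        dev_s = rng.normal(0, 2.0, size=k)
        dev_s -= dev_s.mean()
        dev_d = rng.normal(0, 2.0, size=k)
        dev_d -= dev_d.mean()
        smoke = (np.arange(k) < rec.smoke_sum).astype(int)
        med = (np.arange(k) < rec.med_sum).astype(int)
        for v in range(k):
            rows.append({
                "subject_id": rec.subject_id, "pedigree_id": rec.pedigree_id,
                "visit": v + 1, "age": rec.age_mean + offsets[v],
                "smoke": smoke[v], "medicine": med[v], "gender": rec.gender,
                "SBP": rec.sbp_mean + dev_s[v], "DBP": rec.dbp_mean + dev_d[v],
            })
    return pd.DataFrame(rows)


_GT = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_fixture(cohort: SimCohort, prefix: str) -> tuple[str, str]:
    """Write a cohort as a VCF + long-format phenotype CSV fixture pair."""
    gm = cohort.genotypes
    vcf_path = f"{prefix}.vcf"
    with open(vcf_path, "w", encoding="utf-8") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=pbiscan-simulate\n")
        fh.write('##contig=<ID=3>\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.samples) + "\n")
        for s in range(gm.n_snps):
            gts = [_GT.get(d, "./.") for d in gm.dosages[s]]
            fh.write(f"{gm.chrom[s]}\t{gm.pos[s]}\t{gm.snp_ids[s]}\t{gm.ref[s]}\t"
                     f"{gm.alt[s]}\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n")
    pheno_path = f"{prefix}_pheno.csv"
    longitudinal_table(cohort).to_csv(pheno_path, index=False)
    return vcf_path, pheno_path


def _one_replicate(config: SimConfig, rep: int, schemes: Sequence[str],
                   B: int, seed: int) -> dict[str, float]:
    """p-values (per scheme + LRM) for the causal SNP of one fresh cohort."""
    cfg = replace(config, seed=int(
        np.random.default_rng(derive_seed(seed, config.model, rep)).integers(2**31)
    ))
    cohort = simulate_cohort(cfg)
    sub = cohort.subjects
    g = _flip_to_minor(cohort.genotypes.dosages[cohort.causal_index or 0])
    e = sub["env_medicine"].to_numpy(dtype=float)
    y = sub["dbp_mean"].to_numpy(dtype=float)
    ped = sub["pedigree_id"].to_numpy()
    out: dict[str, float] = {}
    scores = gxe_scores(y, g, e)
    g_codes = g.astype(int)
    e_codes = e.astype(int)
    for scheme in schemes:
        plan = PermutationPlan(scheme=scheme, B=B,
                               seed=derive_seed(seed, config.model, rep, scheme))
        out[f"pbi_{scheme}"] = gxe_permutation_pvalue(
            y, g_codes, e_codes, scores.i_gxe, pedigree_of=ped, plan=plan)
    try:
        out["lrm"] = lrm_interaction_test(y, g, e).p3
    except RankDeficientDesignError:
        out["lrm"] = float("nan")
    return out


def power_experiment(
    configs: dict[str, SimConfig] | Sequence[SimConfig],
    B: int = 199,
    replicates: int = 500,
    alpha: float = 0.05,
    schemes: Sequence[str] = ("global", "local", "residual"),
    seed: int = 0,
) -> pd.DataFrame:
    """Empirical rejection rates for PBI (per scheme) and the LRM comparator.

    For each configuration, ``replicates`` independent cohorts are
    simulated and tested at the causal SNP; the table reports the
    fraction of replicates with p <= alpha per method, with the
    binomial Monte-Carlo standard error.  Under a ``null`` config the
    rates estimate type-I error; under signal models, power.
    """
    if not isinstance(configs, dict):
        configs = {c.model: c for c in configs}
    methods = [f"pbi_{s}" for s in schemes] + ["lrm"]
    records = []
    for label, config in configs.items():
        hits = {m: 0 for m in methods}
        valid = {m: 0 for m in methods}
        for rep in range(replicates):
            ps = _one_replicate(config, rep, schemes, B, seed)
            for m in methods:
                if not np.isnan(ps[m]):
                    valid[m] += 1
                    hits[m] += ps[m] <= alpha
        for m in methods:
            n_ok = valid[m]
            p_hat = hits[m] / n_ok if n_ok else float("nan")
            records.append({
                "label": label, "model": config.model, "method": m,
                "replicates": n_ok, "rejections": hits[m], "rate": p_hat,
                "mc_se": float(np.sqrt(p_hat * (1 - p_hat) / n_ok)) if n_ok else float("nan"),
            })
    return pd.DataFrame.from_records(records)
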