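# Methods

## The partition score

For `n` subjects with quantitative outcome `y` and a categorical
partition with cells `i = 1..k`, the association score is

```
I = Σᵢ (nᵢ/n) · (Ȳᵢ − Ȳ)² / (s²ʸ/nᵢ)  =  Σᵢ nᵢ² (Ȳᵢ − Ȳ)² / (n s²ʸ)
```

with `Ȳ` and `s²ʸ` the grand mean and variance. The score is
dimensionless, nonnegative, invariant under affine transforms of `y`
and under relabelling of cells. Two useful closed forms anchor the
implementation: all subjects in one cell give `I = 0`, and all-singleton
cells give `I = (n−1)/n`.

**Variance convention.** `s²ʸ` uses the sample (n−1) denominator,
exposed as `pbiscan.core.VARIANCE_DDOF`. The choice rescales every
score by the constant `(n−1)/n` and cancels exactly in permutation
p-values, because the identical phenotype vector enters the observed
and permuted statistics.

**Empty cells** contribute nothing: the nominal 3×3
genotype-by-environment sum generalizes to "observed levels only", so
binary factors, monomorphic SNPs and unobserved homozygous-minor
classes are handled uniformly.

## The interaction statistic

For genotype dosage G (minor-allele count 0/1/2) and discretized
environment E, `I_T` scores the joint cells, `I_G` and `I_E` the
margins, and

```
I_G×E = I_T − max(I_G, I_E).
```

`I_G×E` may be negative and is reported as-is (never truncated), so the
permutation reference distribution is honest.

A structural property worth knowing: the `nᵢ²` cell weights mean the
score is *not* monotone under partition refinement — splitting a cell
whose sub-cells share a mean halves that structure's contribution. A
consequence is that strong marginal effects drive `I_G×E` negative:
`I_G` keeps the full `nᵢ²` weight of the genotype classes while `I_T`
pays the refinement penalty, so `I_T < I_G` whenever the joint cells
add little beyond the margin. The statistic is therefore most sensitive
to interactions with weak marginal signatures (the setting that
motivates it — its exemplar signal is a variant with no marginal effect
and opposite non-monotone environment profiles per genotype), and has
essentially no power against an interaction riding on large marginal
effects. The simulator's power configurations use marginal-free
interactions for exactly this reason (below).

**Null hypothesis.** Phenotype permutation tests "the phenotype carries
no information about the G×E partition", not "no interaction given the
marginals". An additive G+E signal can therefore shift `I_G×E`'s null
distribution; this is faithful to the method as defined and is
documented rather than corrected.

**Minimum-data guard.** A test is emitted as a flagged null row (no
p-values) when fewer than 10 complete cases remain or either factor has
a single observed level — the statistic is still defined there, but a
permutation p-value is meaningless. SNPs with minor-allele count < 5
are tested but flagged `low_mac`.

## Permutation schemes and p-values

Writing `y_ij` for subject `j` of pedigree `i` and `ȳᵢ.` for the
pedigree mean:

* **global** — permute phenotypes over all subjects; exact when the
  phenotype is exchangeable across the sample.
* **local** — permute within each pedigree; conditions on pedigree
  profiles and stays valid under between-pedigree mean differences.
* **residual** — form `e_ij = y_ij − ȳᵢ.`, permute the residuals over
  all subjects, reconstruct `y*_ij = ȳᵢ. + e*_ij`; additionally assumes
  the residuals share one distribution across pedigrees. Residuals are
  not re-centred before reconstruction (they already sum to zero within
  pedigree, and the grand sum is conserved exactly).

Genotype and environment labels are never permuted. p-values use the
add-one estimator `p = (1 + #{stat_b ≥ obs}) / (1 + B)` — valid (never
anti-conservative), never zero, ties counted conservatively as
exceedances. A permuted draw on which the statistic fails (degenerate
variance) is retried once and otherwise counted as an exceedance with a
logged warning.

Each test's RNG stream is derived from `(base seed, SNP index,
environment, outcome, scheme)` through `numpy.random.SeedSequence`
(string keys hashed with CRC-32), so scan output is byte-identical
across runs, platforms and any parallel execution order. A batched
evaluator computes permuted statistics on blocks of phenotype rows; it
consumes the RNG draw-for-draw identically to the reference
one-at-a-time path and is tested to return identical p-values. Optional
adaptive stopping (quit once 50 exceedances accumulate, checked per
block) is off by default.

## Covariate pipeline

Longitudinal records (up to 4 visits) reduce to one row per subject:
means over non-missing visits for age and the blood-pressure outcomes,
sums for the binary smoking and medication indicators. Discretization:
age → empirical tertiles (quantiles at 1/3 and 2/3, linear
interpolation of order statistics, right-closed intervals); visit
counts → 0/1/≥2 (so the rule generalizes beyond 4 visits); gender →
two levels as-is (the score is label-invariant, ordering is cosmetic).
Genotypes are recoded to minor-allele dosage with the minor allele
determined in the analyzed subjects; an exact 50/50 tie keeps the
reference allele as major. Missingness is handled per test: a subject
missing any of the three values for a (SNP, environment, outcome)
triple is dropped from that test only, and the linear comparator is
fitted on the identical complete-case set.

## The linear-model comparator

Ordinary least squares of `y` on `[1, G, E, G·E]` with a two-sided
t-test on the interaction coefficient (statsmodels). E enters as its
discretized 0/1/2 level by default so both methods see identical
predictors; a raw continuous covariate can be substituted per factor.
The fit deliberately ignores family structure — it is the plain
linear-model baseline, not a mixed model — so its type-I error degrades
under family confounding while the local/residual permutation schemes
do not (the acceptance experiments quantify this).

## Multiple testing

The default Bonferroni denominator is the SNP count only (0.05/62 915 ≈
7.9×10⁻⁷ at chromosome scale), with a `--full-grid-correction` switch
for the stricter SNP×environment×outcome denominator.

## The simulator

`simulate_cohort` draws pedigrees with a shared normal intercept
(`sigma_fam`), Hardy–Weinberg genotypes at the configured MAF,
a uniform three-level environment surfaced as the medication covariate,
background covariates (age, smoking, gender) with no phenotype effect,
and DBP built from one of five models (SBP is always null): `null`;
`marginal_g` (β_g·G); `additive` (β_g·G + β_e·E); `linear_gxe`
(additive plus β_ge·(G−E[G])(E−E[E]) — the product term is centred at
the population means so β_g/β_e control the marginal effects separately
from the interaction; expanding the product recovers the plain
β₃·G·E linear model with shifted marginal coefficients); and
`crossing_gxe`, a 3×3 cell-mean table `δ·u⊗v` with `u` centred under
the Hardy–Weinberg class weights and `v = (1, −2, 1)` centred under the
environment frequencies: both expected marginal profiles are exactly
flat, and the environment response is V-shaped in one genotype group
and inverted-V in the other — a pure interaction invisible to a linear
product term.

Defaults (20 pedigrees × 25 subjects, MAF 0.3, `sigma_fam = sigma_e =
1`, crossing amplitude δ = 0.5; linear rows use β_g = β_e = 0,
β_ge = 0.8) were fixed by a design-time power calculation so the
headline contrasts are decisive at desk scale: at n = 500, B = 199 the
crossing model gives PBI power ≈ 1 vs LRM ≈ α, and the linear model
gives both methods power > 0.9 with LRM ≥ PBI.

Two clustering knobs, both 0 by default, break whole-sample
exchangeability the way real families do: `fst` draws per-pedigree
allele frequencies from the Balding–Nichols beta model (relatives share
alleles), and `env_family_corr` gives a subject the pedigree's shared
environment level with that probability. Both are needed for the
confounding demonstration: with genotypes and environments i.i.d.
across subjects, globally permuting the phenotype is distributionally
equivalent to permuting the labels, so the global scheme stays exact
*no matter how strong the family effect on y is*. The demonstration
conditions — `sigma_fam/sigma_e = 2`, n = 200, `fst = 0.5`,
`env_family_corr = 0.9` — produce global-permutation rejection ≈ 0.20
at α = 0.05 while local permutation stays at the nominal level. Milder
clustering (`fst = 0.2`, `corr = 0.5`) already inflates the linear
comparator (~0.12) while leaving the `I_G×E` permutation test nearly
calibrated — the max-marginal subtraction absorbs much of the
family-aligned structure. Residual permutation's calibration relies on
identically distributed residuals across pedigrees; heteroscedastic
pedigrees degrade it, which is demonstrable with per-pedigree noise
scales but is not asserted as an invariant.

What the simulator does *not* emulate: linkage disequilibrium between
SNPs, genotype imputation uncertainty, within-subject longitudinal
correlation beyond the shared family intercept, and kinship gradations
inside a pedigree (members are exchangeable). Passing calibration and
power checks on these cohorts therefore validates the statistic and the
permutation machinery, not robustness to LD structure or to
non-exchangeable within-family correlation.

## Validation problem sizes

The packaged experiments use cohorts of n = 200 (type-I error and
confounding; 1000 replicates, B = 199) and n = 500 (power; 500
replicates, B = 199), and a 1000-SNP scan at B = 999 for the
determinism check — sizes chosen so the full suite completes in a few
minutes on a single core while keeping Monte-Carlo standard errors
below about 1.6 percentage points at the 5% level. Calibration is
judged against the exact central 99% binomial acceptance band around
α·replicates; power contrasts are judged in units of the joint
Monte-Carlo standard error.

## Numerical and degenerate-input choices

Constant phenotype or n < 2 raises a `DegenerateSampleError` before any
scoring; all subjects in one joint cell returns all-zero scores rather
than an error; multi-allelic sites raise (and are skipped with a count
by the VCF reader); a rank-deficient regression design (e.g. constant
environment after complete-case filtering) flags the row and withholds
the LRM p-value only. Factor levels are sorted before coding so results
are independent of subject order; subject alignment between genotype
and phenotype inputs is by id, never by position.
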