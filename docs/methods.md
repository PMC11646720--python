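# Methods

## The analysis this package implements

The pipeline treats early menopause (EM; natural menopause before 45) as a
binary outcome of a partially genetic liability. A previously estimated set
of SNP weights defines a polygenic risk score, `PRS = Σₙ βₙ·dosageₙ`, on the
raw weighted-sum scale — no z-scoring, so absolute cutoff values carry
meaning across cohorts scored with the same weights. Risk stratification is
operational and rank-based: a woman's percentile in a reference score
distribution, with percentile > 90 labelling her high risk. Discrimination
is summarised by the ROC curve and its area; group differences in
questionnaire variables use the classical two-group toolkit with automatic
exact-test selection.

## Synthetic cohort model

The generator exists so every downstream stage can be exercised and
property-tested without access to restricted genotype data. It encodes the
study conditions it stands in for, not a fitted model of any real cohort.

**Genetics.** Each of `n_snps` (default 290) biallelic SNPs gets an
effect-allele frequency `pⱼ ~ U(0.05, 0.95)` and a weight
`βⱼ ~ N(0, 0.05²)`. Dosages are i.i.d. `Binomial(2, pⱼ)` — genotype
proportions `(1−p)², 2p(1−p), p²`, i.e. Hardy–Weinberg equilibrium with no
linkage disequilibrium between SNPs.

**Liability and age.** Liability is `L = PRS + N(0, σ_e²)` with
`σ_e = 0.85`. Age at menopause is linear in the standardized liability `z`:

```
age = μ − r·σ_age·z + √(1−r²)·σ_age·ε ,   ε ~ N(0,1)
```

with `r = 0.8` (age-signal fraction) and `σ_age = 4.5` years. The intercept
is calibrated analytically, `μ = 45 − σ_age·Φ⁻¹(K)` for target prevalence
`K = 0.13`, so that `P(age < 45) = K` up to binomial noise; with the
defaults `μ ≈ 50.1`, putting the age distribution's peak near 50. EM status
is the indicator `age < 45`. A post-hoc check raises a calibration error
with diagnostics if the achieved prevalence misses the target by more than
six binomial standard errors (floor 1%).

This is the simplest mechanism that yields (a) a unimodal age distribution
peaked near 50, (b) EM prevalence rising monotonically with score
percentile, and (c) a closed-form discrimination target: the score–latent
correlation is `ρ = r·σ_g/√(σ_g² + σ_e²)` with
`σ_g² = Σ 2pⱼ(1−pⱼ)βⱼ²`, and truncated-normal moments give the binormal
AUC prediction `Φ(Δμ/√(σ₁²+σ₀²))` used as an oracle in the tests. The
default parameters imply `ρ ≈ 0.41` and a predicted AUC ≈ 0.72 — the scale
reported for EM PRS validation in an East Asian cohort.

**Covariates.** Questionnaire covariates are drawn conditionally on the
stratum crossing genetic risk (true-PRS percentile > 90) with EM outcome.
The built-in set encodes the designed risk-factor structure: exposures such
as the husband's smoking or heavy drinking, staying up late, premenopausal
COVID-19 vaccination and high family satisfaction are more prevalent in the
intermediate-risk EM stratum than the high-risk EM stratum, whose exposure
profile deliberately mirrors the general-population baseline stratum; a
family history of EM tracks genetic risk instead, and one null factor
(female smoking) is identical everywhere. Spousal items apply only to
married women; unmarried records are missing for those variables and are
dropped pairwise in comparisons. Rates are fixed once at values on the
scale seen in EM questionnaire studies (e.g. husband smokes: 0.18 high-risk
vs 0.52 intermediate-risk among married women).

**What the generator does not emulate.** No linkage disequilibrium, no
X-chromosome or sex-check model, no population stratification or relatedness
beyond injected exact duplicates, no imputation uncertainty beyond a scalar
per-SNP accuracy score, and age is Gaussian rather than left-skewed as real
menopause ages are. Passing tests therefore demonstrate correctness of the
pipeline's logic and calibration under these idealised conditions, not
performance on real cohort data.

**Randomness.** One root seed; per-stage child streams (weights,
frequencies, genotypes, liability, age, covariates) derived by seed
spawning, so cohorts are bit-identical per config and stages are
individually reproducible.

## Quality control

Filters use strict inequalities at their documented thresholds: SNP call
rate < 0.90, imputation accuracy < 0.9 (SNPs with no score are kept and
flagged), sample call rate < 0.90 (configurable; symmetric default), and
pairwise genotype concordance > 0.95 over ≥ 20 mutually non-missing SNPs
flags a cryptic duplicate pair, both members excluded. The pipeline order
is sample filters (duplicates, sample call rate) then SNP filters (call
rate, HWE, imputation score); every exclusion carries exactly one primary
reason and report counts reconcile exactly with matrix dimension changes.

The Hardy–Weinberg test is the exact conditional test: with allele counts
fixed, `P(n_het) ∝ n!·2^n_het / (n_hom_e!·n_het!·n_hom_o!)`, and the
two-sided p sums probabilities ≤ the observed configuration's. A plain tail
sum (no mid-p) is used deliberately: exclusion thresholds as extreme as
10⁻⁷ (controls) and 10⁻¹² (cases) are only meaningful for the exact tail.
A SNP is dropped when either stratum's p-value falls below its threshold.

## Scoring

Allele harmonization re-expresses dosages as counts of each weight's effect
allele: direct match kept; other-allele match complements the dosage
(d → 2−d) unless the SNP is strand-ambiguous (A/T, C/G), in which case a
needed flip cannot be distinguished from a strand difference and the SNP is
dropped; otherwise a strand-complement match is accepted. Missing dosages
default to mean imputation with `2p̂` from the cohort's non-missing calls
(drop-SNP and fail policies available); a sample missing every SNP has an
undefined score. Percentiles use the empirical CDF with ties counted
(`100·#{ref ≤ x}/n`), the natural convention for "percentile > 90" rules.

## Risk model

AUC uses the rank (Mann–Whitney) formulation with midrank tie correction;
the curve itself is a full threshold sweep. The default cutoff method is
Youden's J (ties broken toward higher specificity, hence the higher
threshold), with a fixed-percentile override reproducing the operational
percentile-90 rule; both the cutoff value and its reference percentile are
reported. Odds ratios by percentile bin compare each bin `(lo, hi]` against
the 40–60% average-risk band with Woolf CIs; a zero cell triggers the
Haldane–Anscombe 0.5 correction and is flagged. Percentile bins are defined
on the analyzed cohort's own empirical distribution. One published
formulation inverts the cutoff's direction (a *lower* score meaning high
risk); this package follows the percentile-above-cutoff rule throughout,
consistent with prevalence rising in score percentile.

## Group-comparison statistics

Pearson's χ² is computed without continuity correction — verified to
reproduce the published statistics this toolkit is modelled on. When any
expected cell count is below 5, the exact test is selected automatically:
Fisher for 2×2, Freeman–Halton for r×c (exhaustive enumeration over tables
with fixed margins, guarded at N ≤ 500 / 5·10⁶ tables, with a seeded
Monte-Carlo fallback via margin-preserving table sampling). Two-sided exact
p-values follow the "probability ≤ observed" convention, with a 1+10⁻⁷
relative tolerance so floating-point noise cannot split exact ties. The
t-test is the classical pooled-variance Student form (Welch behind a flag),
offered both from raw samples and from printed group summaries. No multiple
-testing correction is applied by default, matching the exploratory design
the toolkit mirrors; report formatting rounds statistics to 2 dp and p to
3 dp with a `<.001` floor.

## Numerical and testing notes

- Exact tests are validated against independent enumeration oracles written
  with integer/rational arithmetic (exact tie handling): exhaustively for
  all 2×2 tables with N ≤ 40 and all HWE configurations with N ≤ 50, plus
  random larger tables, all within 10⁻¹⁰.
- Structural pipeline tests run at study scale — a 20,000-sample reference
  cohort and a 99-case / 1,027-control validation split — sizes chosen to
  make binomial/AUC standard errors small relative to the tested effects
  while keeping the suite fast.
- Cohort-specific published values (AUC 0.723, a raw-scale cutoff of
  45.706, top-5% OR 5.75, specific high-risk proportions) depend on
  unreleased genotypes and weights; they are covered structurally (same
  scale, same monotonicity, calibrated prevalence), not reproduced
  numerically.
- Degenerate inputs fail loudly: zero-margin tables, single-class AUC,
  empty references, all-missing samples and invalid configs raise typed
  exceptions rather than returning silent defaults.
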