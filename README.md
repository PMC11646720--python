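# emprs

A polygenic-risk-score (PRS) pipeline for **early menopause** (EM) risk
stratification, written for reproductive-genetics analysts who want the full
chain — genotype quality control, scoring, percentile-based classification
and case-control statistics — as tested, scriptable Python rather than a
one-off analysis.

Early menopause (natural menopause before age 45) has a substantial
polygenic component. Given a table of GWAS-derived SNP weights, each woman's
score is the weighted sum of her effect-allele dosages

```
PRS = β₁·SNP₁ + β₂·SNP₂ + … + βₙ·SNPₙ ,   SNPₙ ∈ {0, 1, 2}
```

where `SNPₙ` counts copies of the effect allele (homozygous non-risk,
heterozygous, homozygous risk) and `βₙ` is the SNP's weight. Women are
ranked against a reference score distribution; a percentile strictly above
90 labels a woman **high risk**, otherwise **intermediate risk**. The
discriminative value of the score is measured by ROC/AUC, a Youden-J or
fixed-percentile cutoff, and odds ratios of EM per percentile bin against
the average-risk 40–60% band. High- and intermediate-risk groups are then
compared questionnaire variable by variable with the classical toolkit:
Pearson χ² (no continuity correction), Fisher / Freeman–Halton exact tests
when expected cell counts drop below 5, Woolf (logit) confidence intervals
for odds ratios, and the pooled-variance two-sample t-test.

Because real genotypes of this kind are not redistributable, the package
includes a first-class **synthetic cohort generator**: a liability-threshold
model (PRS + Gaussian noise) mapped linearly to age at menopause, calibrated
to a target EM prevalence of 13% with the age distribution peaked near 50,
plus stratum-dependent questionnaire covariates and a QC-artifact injector
(missingness, cryptic duplicates, low imputation scores) whose manifest
makes every filter exactly testable.

## Modules

| module | what it does |
|---|---|
| `emprs.simulate` | synthetic cohorts: weights, HWE genotypes, liability → age → EM status, covariates, artifact injection |
| `emprs.qc` | call-rate / HWE-exact / imputation-score / duplicate filters with a reconciled report |
| `emprs.score` | allele harmonization, PRS, reference distribution, empirical percentiles |
| `emprs.riskmodel` | prevalence by percentile, ROC/AUC, cutoff selection, classification, OR by bin |
| `emprs.stats` | χ², Fisher, Freeman–Halton, Woolf OR CI, Student t, automatic test selection, Table-style reports |
| `emprs.io`, `emprs.cli` | VCF/TSV/YAML round trips and the `emprs` command-line pipeline |

## Worked example

```python
import numpy as np
from emprs import simulate, score, riskmodel, stats

# a 20,000-woman reference cohort at 13% EM prevalence
cfg = simulate.SimulationConfig(n_samples=20_000, target_prevalence=0.13, seed=7)
cohort = simulate.simulate_cohort(cfg)
status = cohort.phenotypes["em_status"].to_numpy()
prs = score.compute_prs(cohort.genotypes, cohort.weights)["prs"].to_numpy()

print(round(status.mean(), 4))                      # 0.1321  — empirical prevalence
roc = riskmodel.roc_auc(prs, status)
print(round(roc.auc, 3))                            # 0.713   — PRS discrimination
ref = score.build_reference(prs)
labels = riskmodel.classify(
    score.compute_prs(cohort.genotypes, cohort.weights), ref, cutoff_percentile=90)
print((labels["label"] == "high").mean())           # 0.1     — by construction
table = riskmodel.or_by_percentile_bin(prs, status)
print(round(table.iloc[-1]["odds_ratio"], 2))       # 4.96    — top 5% vs 40–60% band
```

The empirical prevalence lands on the 13% target (binomial noise only), the
AUC agrees with the binormal prediction for the configured genetic
signal-to-noise ratio (≈0.71), exactly 10% of a self-referenced cohort is
labelled high risk, and EM odds rise monotonically with score percentile —
roughly five-fold in the top 5% versus the average-risk band.

Contingency statistics work directly on counts:

```python
res = stats.pearson_chi2([[36, 63], [135, 892]])
orr = stats.odds_ratio_woolf([[36, 63], [135, 892]])
print(round(res.statistic, 2), round(orr.odds_ratio, 2))   # 37.79 3.78
print(round(orr.ci_low, 2), round(orr.ci_high, 2))         # 2.41 5.91
```

The same stages are available from a shell:

```bash
emprs simulate --seed 7 --n-samples 2000 --out-dir cohort/
emprs qc --dosages cohort/dosages.tsv --phenotypes cohort/phenotypes.tsv \
         --weights cohort/weights.tsv --out-dir cohort/qc/
emprs score --dosages cohort/qc/dosages.qc.tsv --weights cohort/weights.tsv \
            --out cohort/scores.tsv
emprs calibrate --scores cohort/scores.tsv --phenotypes cohort/phenotypes.tsv \
                --out cohort/calibration.json
emprs classify --scores cohort/scores.tsv --out cohort/labels.tsv
```

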