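"""Synthetic cohort generator with liability-threshold genetics.

Generates everything the downstream pipeline consumes: a GWAS-style SNP
weight table, Hardy–Weinberg genotype dosages, a liability built from the
true PRS plus Gaussian noise, an age at menopause linear in the standardized
liability (calibrated so the fraction below the early-menopause threshold
matches a target prevalence), questionnaire covariates whose exposure rates
differ between genetic-risk strata, and a QC-artifact injector (missingness,
cryptic duplicates, low imputation scores) with a manifest for exact test
assertions.

The default configuration emulates the reference study conditions: 290 SNPs,
~13% early-menopause prevalence, age-at-menopause distribution peaked near
50 with the threshold at 45 years, and a genetic signal whose theoretical
score-liability correlation (~0.41) puts the PRS discrimination near
AUC 0.72.

All randomness flows from one root seed through named per-stage child
streams, so each stage is reproducible on its own and the full cohort is
bit-identical for a given config.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.stats as sps

from .errors import CalibrationError, InvalidConfigError
from .genotypes import GenotypeMatrix

__all__ = [
    "CovariateSpec",
    "SimulationConfig",
    "SyntheticCohort",
    "ArtifactManifest",
    "default_covariate_specs",
    "simulate_weights",
    "simulate_genotypes",
    "assign_phenotypes",
    "simulate_cohort",
    "simulate_validation_cohort",
    "inject_artifacts",
    "theoretical_prs_liability_corr",
    "liability_binormal_auc",
]

_BASES = np.array(["A", "C", "G", "T"])
_STRATA = ("high_em", "intermediate_em", "high_normal", "intermediate_normal")


@dataclass
class CovariateSpec:
    """One questionnaire covariate and its per-stratum generating law.

    ``kind`` is ``"binary"`` (params: exposure probability), ``"ordinal"``
    (params: probability vector over ``levels``) or ``"continuous"``
    (params: ``(mean, sd)``). ``params`` maps stratum name — combinations of
    genetic-risk group and menopause outcome, e.g. ``"high_em"`` — to the
    stratum's parameters; a ``"default"`` entry backstops missing strata.
    ``applicable_if`` names a previously generated binary covariate that
    gates applicability (e.g. spousal items for married women only);
    non-applicable records are missing.
    """

    name: str
    kind: str
    params: dict
    levels: list[str] | None = None
    applicable_if: str | None = None

    def stratum_params(self, stratum: str):
        if stratum in self.params:
            return self.params[stratum]
        if "default" in self.params:
            return self.params["default"]
        raise InvalidConfigError(f"covariate {self.name!r}: no params for stratum {stratum!r}")


def default_covariate_specs() -> list[CovariateSpec]:
    """Questionnaire covariates with the assumed risk-factor structure.

    Risk factors are more prevalent in the intermediate-risk EM stratum than
    in the high-risk EM stratum, and the high-risk EM stratum mirrors the
    intermediate-risk normal-menopause stratum (the general-population
    baseline); one null factor (female smoking) is identical everywhere.
    Exposure rates echo the scale seen in early-menopause questionnaire
    studies.
    """
    def binary(name, p_high_em, p_int_em, applicable_if=None):
        return CovariateSpec(
            name=name,
            kind="binary",
            params={
                "high_em": p_high_em,
                "intermediate_em": p_int_em,
                # high-risk EM mirrors the general-population baseline
                "intermediate_normal": p_high_em,
                "high_normal": p_high_em,
            },
            applicable_if=applicable_if,
        )

    return [
        CovariateSpec(
            name="height_cm",
            kind="continuous",
            params={
                "high_em": [160.6, 4.6],
                "intermediate_em": [162.9, 5.8],
                "default": [162.9, 5.5],
            },
        ),
        binary("married", 0.94, 0.94),
        CovariateSpec(
            name="family_satisfaction",
            kind="ordinal",
            levels=["dissatisfied", "average", "relatively_satisfied", "very_satisfied"],
            params={
                "high_em": [0.02, 0.16, 0.72, 0.10],
                "intermediate_em": [0.06, 0.10, 0.55, 0.29],
                "default": [0.02, 0.16, 0.72, 0.10],
            },
        ),
        binary("covid_vaccination", 0.75, 0.92),
        binary("family_history_em", 0.31, 0.13),
        binary("husband_smokes", 0.18, 0.52, applicable_if="married"),
        binary("husband_drinks_heavily", 0.12, 0.53, applicable_if="married"),
        binary("stays_up_late", 0.64, 0.83),
        binary("female_smoking", 0.05, 0.05),
    ]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Attributes
    ----------
    n_snps, n_samples
        Score size and cohort size.
    allele_freq_range
        Effect-allele frequencies are drawn uniformly in this open interval.
    effect_scale
        SD of the Normal(0, effect_scale²) SNP weights.
    liability_noise_sd
        SD of the non-genetic liability component added to the true PRS.
    target_prevalence
        Desired fraction with age at menopause below ``em_age_threshold``.
    age_mean, age_sd
        Nominal location and spread (years) of age at menopause; the
        location is re-calibrated from the prevalence target (the default
        parameters land the calibrated mean at ~50.1 y, i.e. on age_mean).
    age_signal_fraction
        Correlation between standardized liability and the age-determining
        latent; the rest of the age variance is independent noise.
    em_age_threshold
        Early-menopause age threshold in years (45).
    covariate_specs
        Questionnaire covariates; defaults to :func:`default_covariate_specs`.
    high_risk_percentile
        True-PRS percentile above which a sample counts as the high-risk
        stratum when conditioning covariates.
    seed
        Root seed for all stages.
    """

    n_snps: int = 290
    n_samples: int = 1000
    allele_freq_range: tuple[float, float] = (0.05, 0.95)
    effect_scale: float = 0.05
    liability_noise_sd: float = 0.85
    target_prevalence: float = 0.13
    age_mean: float = 50.0
    age_sd: float = 4.5
    age_signal_fraction: float = 0.8
    em_age_threshold: float = 45.0
    covariate_specs: list[CovariateSpec] = field(default_factory=default_covariate_specs)
    high_risk_percentile: float = 90.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise InvalidConfigError("n_snps must be at least 1")
        if self.n_samples < 1:
            raise InvalidConfigError("n_samples must be at least 1")
        lo, hi = self.allele_freq_range
        if not (0 < lo <= hi < 1):
            raise InvalidConfigError("allele_freq_range must lie inside (0, 1)")
        if not 0 < self.target_prevalence < 1:
            raise InvalidConfigError("target_prevalence must be in (0, 1)")
        if self.effect_scale < 0:
            raise InvalidConfigError("effect_scale must be non-negative")
        if self.liability_noise_sd <= 0:
            raise InvalidConfigError("liability_noise_sd must be positive")
        if not 0 < self.age_signal_fraction <= 1:
            raise InvalidConfigError("age_signal_fraction must be in (0, 1]")
        if self.age_sd <= 0:
            raise InvalidConfigError("age_sd must be positive")

    def stage_rng(self, stage: str) -> np.random.Generator:
        """Named per-stage RNG stream derived from the root seed."""
        stages = ["weights", "freqs", "genotypes", "liability", "age", "covariates", "artifacts"]
        children = np.random.SeedSequence(self.seed).spawn(len(stages))
        return np.random.default_rng(children[stages.index(stage)])


@dataclass
class SyntheticCohort:
    """A simulated cohort: genotypes, weights, phenotypes and the truth."""

    genotypes: GenotypeMatrix
    weights: pd.DataFrame
    phenotypes: pd.DataFrame
    true_liability: np.ndarray
    true_prs: np.ndarray
    config: SimulationConfig
    meta: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return self.genotypes.n_samples


def simulate_weights(config: SimulationConfig) -> pd.DataFrame:
    """Draw a GWAS-style weight table: snp_id, effect/other allele, β.

    Weights are Normal(0, effect_scale²); alleles are a random ordered pair
    of distinct bases per SNP. Deterministic given the config seed.
    """
    rng = config.stage_rng("weights")
    n = config.n_snps
    snp_ids = np.array([f"rs{1_000_000 + i}" for i in range(n)], dtype=object)
    ea_idx = rng.integers(0, 4, size=n)
    oa_idx = (ea_idx + rng.integers(1, 4, size=n)) % 4
    beta = rng.normal(0.0, config.effect_scale, size=n)
    return pd.DataFrame(
        {
            "snp_id": snp_ids,
            "effect_allele": _BASES[ea_idx],
            "other_allele": _BASES[oa_idx],
            "beta": beta,
        }
    )


def simulate_genotypes(weights: pd.DataFrame, config: SimulationConfig) -> GenotypeMatrix:
    """Draw Hardy–Weinberg dosages for every SNP in the weight table.

    Each SNP gets an effect-allele frequency p uniform in
    ``allele_freq_range``; dosages are i.i.d. Binomial(2, p), equivalent to
    genotype probabilities (1−p)², 2p(1−p), p² for 0/1/2. Dosages count the
    weight table's effect allele, so no harmonization is needed downstream.
    """
    lo, hi = config.allele_freq_range
    freqs = config.stage_rng("freqs").uniform(lo, hi, size=len(weights))
    rng = config.stage_rng("genotypes")
    dosages = rng.binomial(2, freqs, size=(config.n_samples, len(weights))).astype(float)
    return GenotypeMatrix(
        sample_ids=np.array([f"S{i:06d}" for i in range(config.n_samples)], dtype=object),
        snp_ids=weights["snp_id"].to_numpy(dtype=object),
        dosages=dosages,
        effect_allele=weights["effect_allele"].to_numpy(dtype=object),
        other_allele=weights["other_allele"].to_numpy(dtype=object),
        # directly-assayed panel: high accuracy scores, drawn after the dosages
        imputation_score=rng.uniform(0.95, 1.0, size=len(weights)),
    )


def theoretical_prs_liability_corr(weights: pd.DataFrame, freqs, config: SimulationConfig) -> float:
    """Correlation between the PRS and the age-determining latent.

    Under the generating model the genetic liability variance is
    ``σ_g² = Σ 2 p_j (1−p_j) β_j²``; the latent driving case status is
    ``r·z + √(1−r²)·ε`` with ``z`` the standardized liability, so the
    score-latent correlation is ``r·σ_g / √(σ_g² + σ_e²)``.
    """
    freqs = np.asarray(freqs, dtype=float)
    beta = weights["beta"].to_numpy(dtype=float)
    var_g = float(np.sum(2 * freqs * (1 - freqs) * beta**2))
    sd_l = math.sqrt(var_g + config.liability_noise_sd**2)
    if sd_l == 0:
        return 0.0
    return config.age_signal_fraction * math.sqrt(var_g) / sd_l


def liability_binormal_auc(rho: float, prevalence: float) -> float:
    """Predicted PRS AUC under the liability-threshold model, binormal form.

    Cases are draws with latent above the prevalence threshold
    ``t = Φ⁻¹(1 − K)``. Truncated-normal moments give the case/control score
    means and variances; the binormal formula
    ``AUC = Φ(Δμ / √(σ₁² + σ₀²))`` turns them into a predicted AUC.
    """
    if rho == 0:
        return 0.5
    t = sps.norm.ppf(1 - prevalence)
    phi_t = sps.norm.pdf(t)
    lam1 = phi_t / prevalence        # E[Z | Z > t]
    lam0 = -phi_t / (1 - prevalence)  # E[Z | Z ≤ t]
    mu1, mu0 = rho * lam1, rho * lam0
    v1 = 1 - rho**2 * lam1 * (lam1 - t)
    v0 = 1 - rho**2 * (lam0 * (lam0 - t))
    return float(sps.norm.cdf((mu1 - mu0) / math.sqrt(v1 + v0)))


def _draw_covariates(
    specs: list[CovariateSpec],
    stratum: np.ndarray,
    rng: np.random.Generator,
) -> pd.DataFrame:
    n = len(stratum)
    out: dict[str, np.ndarray] = {}
    for spec in specs:
        col = np.empty(n, dtype=object)
        for s in np.unique(stratum):
            mask = stratum == s
            k = int(mask.sum())
            p = spec.stratum_params(str(s))
            if spec.kind == "binary":
                col[mask] = (rng.random(k) < float(p)).astype(int)
            elif spec.kind == "ordinal":
                probs = np.asarray(p, dtype=float)
                if not math.isclose(probs.sum(), 1.0, abs_tol=1e-9):
                    raise InvalidConfigError(f"{spec.name}: ordinal probs must sum to 1")
                levels = spec.levels or [str(i) for i in range(len(probs))]
                col[mask] = rng.choice(levels, size=k, p=probs)
            elif spec.kind == "continuous":
                mean, sd = p
                col[mask] = rng.normal(mean, sd, size=k)
            else:
                raise InvalidConfigError(f"unknown covariate kind {spec.kind!r}")
        if spec.applicable_if is not None:
            gate = out.get(spec.applicable_if)
            if gate is None:
                raise InvalidConfigError(
                    f"{spec.name}: gating covariate {spec.applicable_if!r} not yet generated"
                )
            col = np.where(np.asarray(gate, dtype=float) == 1, col, None)
        out[spec.name] = col
    df = pd.DataFrame(out)
    for spec in specs:
        if spec.kind == "continuous":
            df[spec.name] = df[spec.name].astype(float)
    return df


def assign_phenotypes(
    genotypes: GenotypeMatrix, weights: pd.DataFrame, config: SimulationConfig
) -> SyntheticCohort:
    """Build liability, age at menopause, EM status and covariates.

    Liability is ``PRS + Normal(0, liability_noise_sd)``. Age at menopause
    is linear in the standardized liability with slope ``−r·age_sd``
    (``r = age_signal_fraction``) plus independent Gaussian noise
    ``√(1−r²)·age_sd``, around an intercept calibrated analytically so that
    ``P(age < em_age_threshold) = target_prevalence``; EM status is the
    indicator ``age < em_age_threshold``. The achieved prevalence is checked
    against the target (6 standard binomial errors plus a 1% floor) and a
    :class:`CalibrationError` with diagnostics is raised on failure.

    Covariates are drawn conditioned on the stratum crossing the genetic
    risk group (true-PRS percentile above ``high_risk_percentile``) with the
    EM outcome.
    """
    if np.isnan(genotypes.dosages).any():
        raise InvalidConfigError("assign_phenotypes expects complete genotypes; "
                                 "inject missingness afterwards")
    n = genotypes.n_samples
    beta = weights.set_index("snp_id").loc[genotypes.snp_ids, "beta"].to_numpy(dtype=float)
    prs = genotypes.dosages @ beta
    liab_rng = config.stage_rng("liability")
    liability = prs + liab_rng.normal(0.0, config.liability_noise_sd, size=n)
    sd = liability.std()
    z = (liability - liability.mean()) / (sd if sd > 0 else 1.0)

    r = config.age_signal_fraction
    age_rng = config.stage_rng("age")
    noise = math.sqrt(1 - r**2) * config.age_sd * age_rng.normal(size=n)
    signal = -r * config.age_sd * z
    intercept = config.em_age_threshold - config.age_sd * sps.norm.ppf(config.target_prevalence)
    age = intercept + signal + noise
    em = (age < config.em_age_threshold).astype(int)

    achieved = float(em.mean())
    tol = max(6 * math.sqrt(config.target_prevalence * (1 - config.target_prevalence) / n), 0.01)
    if abs(achieved - config.target_prevalence) > tol:
        raise CalibrationError(
            "calibrated intercept failed to reach the target prevalence",
            diagnostics={
                "achieved_prevalence": achieved,
                "target_prevalence": config.target_prevalence,
                "tolerance": tol,
                "intercept": intercept,
                "n_samples": n,
            },
        )

    prs_rank_pct = 100.0 * sps.rankdata(prs, method="max") / n
    high = prs_rank_pct > config.high_risk_percentile
    stratum = np.where(
        high,
        np.where(em == 1, "high_em", "high_normal"),
        np.where(em == 1, "intermediate_em", "intermediate_normal"),
    )
    covariates = _draw_covariates(config.covariate_specs, stratum, config.stage_rng("covariates"))

    phenotypes = pd.DataFrame(
        {
            "sample_id": genotypes.sample_ids,
            "em_status": em,
            "age_at_menopause": age,
            "age_observed": np.ones(n, dtype=bool),
            "risk_stratum": stratum,
        }
    )
    phenotypes = pd.concat([phenotypes, covariates], axis=1)
    return SyntheticCohort(
        genotypes=genotypes,
        weights=weights,
        phenotypes=phenotypes,
        true_liability=liability,
        true_prs=prs,
        config=config,
        meta={"age_intercept": intercept, "achieved_prevalence": achieved},
    )


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Weights → genotypes → phenotypes, all from one config."""
    weights = simulate_weights(config)
    genotypes = simulate_genotypes(weights, config)
    return assign_phenotypes(genotypes, weights, config)


def simulate_validation_cohort(
    weights: pd.DataFrame,
    config: SimulationConfig,
    n_cases: int,
    n_controls: int,
    seed: int,
) -> SyntheticCohort:
    """Case/control validation cohort with fixed counts and the same score.

    Simulates a pool under ``config`` (re-seeded with ``seed``) large enough
    to contain the requested numbers of EM cases and controls, then keeps
    the first ``n_cases`` cases and ``n_controls`` non-cases. Control ages
    are masked as unobserved, mimicking a general-population control group
    whose menopause timing is unknown (their EM status stays 0).
    """
    prev = config.target_prevalence
    pool_n = int(max(n_cases / prev, n_controls / (1 - prev)) * 1.4) + 200
    pool_cfg = replace(config, n_samples=pool_n, seed=seed)
    genotypes = simulate_genotypes(weights, pool_cfg)
    pool = assign_phenotypes(genotypes, weights, pool_cfg)

    em = pool.phenotypes["em_status"].to_numpy()
    case_idx = np.flatnonzero(em == 1)[:n_cases]
    ctrl_idx = np.flatnonzero(em == 0)[:n_controls]
    if len(case_idx) < n_cases or len(ctrl_idx) < n_controls:
        raise CalibrationError(
            "simulated pool too small for the requested case/control counts",
            diagnostics={"pool_n": pool_n, "cases_available": int((em == 1).sum())},
        )
    keep = np.concatenate([case_idx, ctrl_idx])
    phen = pool.phenotypes.iloc[keep].reset_index(drop=True).copy()
    is_ctrl = np.arange(len(keep)) >= len(case_idx)
    phen.loc[is_ctrl, "age_at_menopause"] = np.nan
    phen.loc[is_ctrl, "age_observed"] = False
    return SyntheticCohort(
        genotypes=pool.genotypes.subset_samples(keep),
        weights=weights,
        phenotypes=phen,
        true_liability=pool.true_liability[keep],
        true_prs=pool.true_prs[keep],
        config=pool_cfg,
        meta=dict(pool.meta, validation_split=(n_cases, n_controls)),
    )


# ---------------------------------------------------------------------------
# QC artifact injection


@dataclass
class ArtifactManifest:
    """Exactly what :func:`inject_artifacts` did, for test assertions."""

    missing_counts: dict[str, int] = field(default_factory=dict)  # snp_id -> injected NaNs
    call_rates: dict[str, float] = field(default_factory=dict)    # resulting per-SNP call rate
    duplicate_pairs: list[tuple[str, str]] = field(default_factory=list)
    low_impscore_snps: dict[str, float] = field(default_factory=dict)

    def snps_below_call_rate(self, threshold: float = 0.90) -> set[str]:
        """SNPs whose realized call rate fell strictly below ``threshold``."""
        return {s for s, r in self.call_rates.items() if r < threshold}


def inject_artifacts(
    cohort: SyntheticCohort,
    missing_rate_per_snp: float | dict[str, float] = 0.0,
    n_duplicate_pairs: int = 0,
    n_low_impscore_snps: int = 0,
    seed: int = 0,
) -> tuple[SyntheticCohort, ArtifactManifest]:
    """Copy the cohort with QC-detectable artifacts injected.

    Parameters
    ----------
    missing_rate_per_snp
        Per-SNP Bernoulli missingness rate; a scalar applies to every SNP, a
        mapping ``snp_id → rate`` targets specific SNPs (others untouched).
    n_duplicate_pairs
        Number of cryptic duplicate pairs: each pair picks two distinct
        samples and overwrites the second's genotypes with an exact copy of
        the first's.
    n_low_impscore_snps
        Number of SNPs whose imputation accuracy score is rewritten to a
        value below 0.9 (uniform in [0.5, 0.89]).

    Returns the modified copy and an :class:`ArtifactManifest`. Duplicates
    are created before missingness, so pair concordance over mutually
    observed SNPs stays exactly 1. Requesting more duplicate samples than
    exist raises.
    """
    rng = np.random.default_rng(seed)
    gm = cohort.genotypes.copy()
    manifest = ArtifactManifest()

    if 2 * n_duplicate_pairs > gm.n_samples:
        raise InvalidConfigError("more duplicate pair members than samples")
    if n_duplicate_pairs > 0:
        chosen = rng.choice(gm.n_samples, size=2 * n_duplicate_pairs, replace=False)
        for k in range(n_duplicate_pairs):
            src, dst = int(chosen[2 * k]), int(chosen[2 * k + 1])
            gm.dosages[dst] = gm.dosages[src]
            manifest.duplicate_pairs.append(
                (str(gm.sample_ids[src]), str(gm.sample_ids[dst]))
            )

    if isinstance(missing_rate_per_snp, dict):
        rates = {s: float(r) for s, r in missing_rate_per_snp.items()}
    else:
        rates = {str(s): float(missing_rate_per_snp) for s in gm.snp_ids}
    for snp, rate in rates.items():
        if not 0 <= rate <= 1:
            raise InvalidConfigError(f"missing rate for {snp} outside [0, 1]")
        if rate == 0:
            continue
        j = gm.snp_index(snp)
        mask = rng.random(gm.n_samples) < rate
        gm.dosages[mask, j] = np.nan
        manifest.missing_counts[snp] = int(mask.sum())
    for j, snp in enumerate(gm.snp_ids):
        manifest.call_rates[str(snp)] = float(1.0 - np.isnan(gm.dosages[:, j]).mean())

    if n_low_impscore_snps > gm.n_snps:
        raise InvalidConfigError("more low-imputation-score SNPs than SNPs")
    if n_low_impscore_snps > 0:
        idx = rng.choice(gm.n_snps, size=n_low_impscore_snps, replace=False)
        scores = rng.uniform(0.5, 0.89, size=n_low_impscore_snps)
        gm.imputation_score[idx] = scores
        manifest.low_impscore_snps = {
            str(gm.snp_ids[i]): float(s) for i, s in zip(idx, scores)
        }

    return (
        SyntheticCohort(
            genotypes=gm,
            weights=cohort.weights,
            phenotypes=cohort.phenotypes.copy(),
            true_liability=cohort.true_liability.copy(),
            true_prs=cohort.true_prs.copy(),
            config=cohort.config,
            meta=dict(cohort.meta, artifacts_injected=True),
        ),
        manifest,
    )
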