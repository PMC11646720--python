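"""Sample- and SNP-level genotype quality control.

Filters mirror standard array-genotyping practice: SNPs are dropped for low
assay call rate (< 0.90), for deviation from Hardy–Weinberg equilibrium
(exact conditional test, separate thresholds in controls and cases) and for
low imputation accuracy (< 0.9); samples are dropped for low call rate and
for cryptic duplication (pairwise genotype concordance). All thresholds are
strict ``<`` / ``>`` comparisons and every exclusion is recorded with exactly
one primary reason in a :class:`QCReport`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from math import lgamma

import numpy as np

from .errors import EmptyInputError, InvalidInputError
from .genotypes import GenotypeMatrix

__all__ = [
    "QCReport",
    "hwe_exact_test",
    "snp_call_rate_filter",
    "sample_call_rate_filter",
    "hwe_filter",
    "imputation_score_filter",
    "duplicate_sample_filter",
    "run_qc",
]


@dataclass
class QCReport:
    """Record of exclusions made by one or more QC filters."""

    excluded_samples: list[tuple[str, str]] = field(default_factory=list)
    excluded_snps: list[tuple[str, str]] = field(default_factory=list)
    hwe_pvalues: dict[str, dict[str, float]] = field(default_factory=dict)
    thresholds: dict[str, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    unevaluable_pairs: list[tuple[str, str]] = field(default_factory=list)

    def merge(self, other: "QCReport") -> "QCReport":
        self.excluded_samples += other.excluded_samples
        self.excluded_snps += other.excluded_snps
        self.hwe_pvalues.update(other.hwe_pvalues)
        self.thresholds.update(other.thresholds)
        self.warnings += other.warnings
        self.unevaluable_pairs += other.unevaluable_pairs
        return self

    def excluded_snp_ids(self, reason: str | None = None) -> set[str]:
        return {s for s, r in self.excluded_snps if reason is None or r == reason}

    def excluded_sample_ids(self, reason: str | None = None) -> set[str]:
        return {s for s, r in self.excluded_samples if reason is None or r == reason}


# ---------------------------------------------------------------------------
# Hardy–Weinberg exact test


def hwe_exact_test(n_hom_effect: int, n_het: int, n_hom_other: int) -> float:
    """Exact conditional test of Hardy–Weinberg equilibrium.

    With the total sample size ``n`` and the effect-allele count fixed, the
    heterozygote count follows the exact conditional distribution

    ``P(n_het) ∝ n! · 2^n_het / (n_hom_effect! · n_het! · n_hom_other!)``.

    The two-sided p-value sums the probabilities of every attainable
    heterozygote count whose probability does not exceed the observed one
    (plain tail sum, no mid-p).

    Returns
    -------
    float in (0, 1]. Monomorphic SNPs (a single attainable configuration)
    give p = 1.
    """
    for v in (n_hom_effect, n_het, n_hom_other):
        if int(v) != v or v < 0:
            raise InvalidInputError("genotype counts must be non-negative integers")
    a, h, b = int(n_hom_effect), int(n_het), int(n_hom_other)
    n = a + h + b
    if n < 1:
        raise InvalidInputError("at least one genotype is required")
    n_eff = 2 * a + h  # effect-allele count, fixed margin
    het_max = min(n_eff, 2 * n - n_eff)

    # log-weights over attainable het counts (parity of n_eff preserved)
    hets = np.arange(n_eff % 2, het_max + 1, 2)
    logw = np.array(
        [x * math.log(2) - lgamma((n_eff - x) // 2 + 1) - lgamma(x + 1)
         - lgamma((2 * n - n_eff - x) // 2 + 1) for x in hets]
    )
    logw -= logw.max()
    w = np.exp(logw)
    probs = w / w.sum()
    p_obs = probs[np.flatnonzero(hets == h)[0]]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-9)].sum()))


# ---------------------------------------------------------------------------
# SNP filters


def snp_call_rate_filter(
    genotypes: GenotypeMatrix, threshold: float = 0.90
) -> tuple[GenotypeMatrix, QCReport]:
    """Drop SNPs whose assay call rate is strictly below ``threshold``."""
    if not 0 < threshold <= 1:
        raise InvalidInputError("threshold must be in (0, 1]")
    if genotypes.n_samples == 0 or genotypes.n_snps == 0:
        raise EmptyInputError("cannot filter an empty genotype matrix")
    rates = genotypes.snp_call_rate()
    drop = rates < threshold
    report = QCReport(
        excluded_snps=[(s, "low_call_rate") for s in genotypes.snp_ids[drop]],
        thresholds={"snp_call_rate": threshold},
    )
    return genotypes.subset_snps(~drop), report


def imputation_score_filter(
    genotypes: GenotypeMatrix, threshold: float = 0.9
) -> tuple[GenotypeMatrix, QCReport]:
    """Drop SNPs with imputation accuracy score strictly below ``threshold``.

    SNPs without a score are retained and flagged in the report.
    """
    report = QCReport(thresholds={"imputation_score": threshold})
    scores = genotypes.imputation_score
    if np.isnan(scores).all():
        report.warnings.append("no imputation scores present; matrix unchanged")
        return genotypes.copy(), report
    no_score = np.isnan(scores)
    if no_score.any():
        report.warnings.append(
            f"{int(no_score.sum())} SNPs without an imputation score were retained"
        )
    drop = scores < threshold  # NaN compares False: retained
    report.excluded_snps = [(s, "low_imputation_score") for s in genotypes.snp_ids[drop]]
    return genotypes.subset_snps(~drop), report


def hwe_filter(
    genotypes: GenotypeMatrix,
    case_status: np.ndarray,
    p_controls: float = 1e-7,
    p_cases: float = 1e-12,
) -> tuple[GenotypeMatrix, QCReport]:
    """Drop SNPs out of Hardy–Weinberg equilibrium in either stratum.

    The exact test runs separately in controls and in cases; a SNP is
    excluded when its control p-value is below ``p_controls`` **or** its case
    p-value is below ``p_cases`` (strict ``<``). If a stratum is empty its
    test is skipped with a warning.
    """
    case_status = np.asarray(case_status).astype(bool)
    if len(case_status) != genotypes.n_samples:
        raise InvalidInputError("case_status must be defined for every sample")
    report = QCReport(thresholds={"hwe_p_controls": p_controls, "hwe_p_cases": p_cases})
    strata = {"controls": ~case_status, "cases": case_status}
    pvals: dict[str, dict[str, float]] = {s: {} for s in strata}
    for name, mask in strata.items():
        if not mask.any():
            report.warnings.append(f"no {name}: HWE test skipped in this stratum")
            continue
        counts = genotypes.genotype_counts(mask)
        for j, snp in enumerate(genotypes.snp_ids):
            a, h, b = counts[j]
            if a + h + b == 0:
                continue  # SNP fully missing in stratum
            pvals[name][snp] = hwe_exact_test(a, h, b)
    drop = np.zeros(genotypes.n_snps, dtype=bool)
    for j, snp in enumerate(genotypes.snp_ids):
        pc = pvals["controls"].get(snp)
        pk = pvals["cases"].get(snp)
        if (pc is not None and pc < p_controls) or (pk is not None and pk < p_cases):
            drop[j] = True
    report.excluded_snps = [(s, "hwe_fail") for s in genotypes.snp_ids[drop]]
    report.hwe_pvalues = pvals
    return genotypes.subset_snps(~drop), report


# ---------------------------------------------------------------------------
# Sample filters


def sample_call_rate_filter(
    genotypes: GenotypeMatrix, threshold: float = 0.90
) -> tuple[GenotypeMatrix, QCReport]:
    """Drop samples whose genotype call rate is strictly below ``threshold``."""
    if not 0 < threshold <= 1:
        raise InvalidInputError("threshold must be in (0, 1]")
    rates = genotypes.sample_call_rate()
    drop = rates < threshold
    report = QCReport(
        excluded_samples=[(s, "low_call_rate") for s in genotypes.sample_ids[drop]],
        thresholds={"sample_call_rate": threshold},
    )
    return genotypes.subset_samples(~drop), report


def pairwise_concordance(genotypes: GenotypeMatrix, min_overlap: int = 20):
    """Genotype concordance over mutually non-missing SNPs for every pair.

    Returns ``(i, j, concordance, n_overlap)`` tuples for pairs with at least
    ``min_overlap`` shared non-missing SNPs, plus the list of unevaluable
    pairs.
    """
    d = genotypes.dosages
    obs = ~np.isnan(d)
    results, unevaluable = [], []
    for i in range(genotypes.n_samples - 1):
        both = obs[i] & obs[i + 1:]
        eq = (d[i + 1:] == d[i]) & both
        overlap = both.sum(axis=1)
        conc = np.divide(eq.sum(axis=1), overlap, out=np.zeros(len(overlap)), where=overlap > 0)
        for k in range(len(overlap)):
            j = i + 1 + k
            if overlap[k] < min_overlap:
                unevaluable.append((genotypes.sample_ids[i], genotypes.sample_ids[j]))
            else:
                results.append((i, j, float(conc[k]), int(overlap[k])))
    return results, unevaluable


def duplicate_sample_filter(
    genotypes: GenotypeMatrix,
    concordance_threshold: float = 0.95,
    min_overlap: int = 20,
) -> tuple[GenotypeMatrix, QCReport]:
    """Exclude cryptic duplicate pairs (both members of each flagged pair).

    A pair is flagged when its genotype concordance over mutually non-missing
    SNPs exceeds ``concordance_threshold``. Pairs sharing fewer than
    ``min_overlap`` non-missing SNPs are not evaluable and are logged.
    """
    if genotypes.n_samples < 2:
        raise InvalidInputError("duplicate detection needs at least 2 samples")
    pairs, unevaluable = pairwise_concordance(genotypes, min_overlap=min_overlap)
    drop = np.zeros(genotypes.n_samples, dtype=bool)
    for i, j, conc, _ in pairs:
        if conc > concordance_threshold:
            drop[i] = drop[j] = True
    report = QCReport(
        excluded_samples=[(s, "duplicate") for s in genotypes.sample_ids[drop]],
        thresholds={"duplicate_concordance": concordance_threshold},
        unevaluable_pairs=unevaluable,
    )
    return genotypes.subset_samples(~drop), report


# ---------------------------------------------------------------------------
# Pipeline


def run_qc(
    genotypes: GenotypeMatrix,
    case_status: np.ndarray,
    *,
    snp_call_rate: float = 0.90,
    sample_call_rate: float = 0.90,
    hwe_p_controls: float = 1e-7,
    hwe_p_cases: float = 1e-12,
    imputation_score: float = 0.9,
    duplicate_concordance: float = 0.95,
    min_overlap: int = 20,
) -> tuple[GenotypeMatrix, QCReport]:
    """Full QC pipeline: sample filters first, then SNP filters.

    Order: duplicate exclusion, sample call rate, SNP call rate, HWE
    (case/control-specific thresholds), imputation score. ``case_status`` is
    subset alongside the matrix as samples are removed. A genotypic-sex check
    is not modelled (no X-chromosome data) and is recorded as a warning.
    """
    case_status = np.asarray(case_status).astype(bool)
    report = QCReport(warnings=["genotypic sex check not performed (no X-chromosome model)"])

    gm, rep = duplicate_sample_filter(
        genotypes, concordance_threshold=duplicate_concordance, min_overlap=min_overlap
    )
    report.merge(rep)
    keep = np.isin(genotypes.sample_ids, gm.sample_ids)
    case_status = case_status[keep]

    prev_ids = gm.sample_ids
    gm, rep = sample_call_rate_filter(gm, threshold=sample_call_rate)
    report.merge(rep)
    case_status = case_status[np.isin(prev_ids, gm.sample_ids)]

    gm, rep = snp_call_rate_filter(gm, threshold=snp_call_rate)
    report.merge(rep)
    gm, rep = hwe_filter(gm, case_status, p_controls=hwe_p_controls, p_cases=hwe_p_cases)
    report.merge(rep)
    gm, rep = imputation_score_filter(gm, threshold=imputation_score)
    report.merge(rep)
    return gm, report
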