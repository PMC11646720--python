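"""Polygenic risk scoring and the percentile reference distribution.

The score of an individual is the weighted sum of effect-allele dosages,

    PRS = β₁·SNP₁ + β₂·SNP₂ + … + βₙ·SNPₙ,

where SNPₙ ∈ {0, 1, 2} counts copies of the effect allele and βₙ is the
per-SNP weight from a prior GWAS. Scores are kept on the raw weighted-sum
scale (no z-scoring) so that absolute cutoff values are meaningful.
Percentiles are empirical-CDF percentiles against a reference cohort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EmptyInputError, InvalidConfigError, InvalidInputError
from .genotypes import GenotypeMatrix

__all__ = [
    "validate_weights",
    "HarmonizationLog",
    "harmonize_alleles",
    "compute_prs",
    "ReferenceDistribution",
    "build_reference",
    "percentile_of",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


def validate_weights(weights: pd.DataFrame) -> pd.DataFrame:
    """Validate a weight table (columns ``snp_id``, ``effect_allele``, ``beta``).

    An optional ``other_allele`` column disambiguates harmonization. Returns
    the validated frame (unchanged).
    """
    required = {"snp_id", "effect_allele", "beta"}
    missing = required - set(weights.columns)
    if missing:
        raise InvalidInputError(f"weight table missing columns: {sorted(missing)}")
    if weights["snp_id"].duplicated().any():
        raise InvalidInputError("weight table has duplicate snp ids")
    if not np.isfinite(weights["beta"].to_numpy(dtype=float)).all():
        raise InvalidInputError("weights must be finite")
    return weights


@dataclass
class HarmonizationLog:
    """Which SNPs were kept as-is, dosage-flipped, or dropped (and why)."""

    kept: list[str] = field(default_factory=list)
    flipped: list[str] = field(default_factory=list)
    dropped: dict[str, str] = field(default_factory=dict)  # snp_id -> reason


def harmonize_alleles(
    genotypes: GenotypeMatrix, weights: pd.DataFrame
) -> tuple[GenotypeMatrix, HarmonizationLog]:
    """Re-express dosages as counts of each weight's effect allele.

    For every SNP shared between the matrix and the weight table:

    - genotype effect allele already matches → kept unchanged;
    - genotype *other* allele matches the weight's effect allele → dosage
      complemented (d → 2 − d) and allele labels swapped;
    - a match only exists through strand complement → accepted unless the
      SNP is strand-ambiguous (A/T or C/G), which is dropped;
    - no match at all → dropped.

    The output matrix contains exactly the retained SNPs, in weight-table
    order. Raises if no SNPs overlap.
    """
    validate_weights(weights)
    wt = weights.set_index("snp_id")
    shared = [s for s in wt.index if s in set(genotypes.snp_ids)]
    if not shared:
        raise InvalidInputError("no overlapping snp ids between genotypes and weights")

    log = HarmonizationLog()
    log.dropped.update({s: "not_in_genotypes" for s in wt.index if s not in set(shared)})
    keep_idx: list[int] = []
    flip: list[bool] = []
    for snp in shared:
        j = genotypes.snp_index(snp)
        ea, oa = genotypes.effect_allele[j], genotypes.other_allele[j]
        w_ea = wt.at[snp, "effect_allele"]
        ambiguous = (ea, oa) in _AMBIGUOUS_PAIRS
        if ea == w_ea:
            # direct match: same strand assumed, no flip needed
            keep_idx.append(j); flip.append(False); log.kept.append(snp)
        elif oa == w_ea:
            # a flip is needed; for A/T and C/G SNPs this is indistinguishable
            # from a strand difference, so the SNP cannot be trusted
            if ambiguous:
                log.dropped[snp] = "strand_ambiguous"
            else:
                keep_idx.append(j); flip.append(True); log.flipped.append(snp)
        elif _COMPLEMENT.get(ea) == w_ea:
            keep_idx.append(j); flip.append(False); log.kept.append(snp)
        elif _COMPLEMENT.get(oa) == w_ea:
            keep_idx.append(j); flip.append(True); log.flipped.append(snp)
        else:
            log.dropped[snp] = "allele_mismatch"
    if not keep_idx:
        raise InvalidInputError("no SNPs could be harmonized")

    out = genotypes.subset_snps(np.asarray(keep_idx))
    flip_arr = np.asarray(flip)
    out.dosages[:, flip_arr] = 2.0 - out.dosages[:, flip_arr]
    ea = out.effect_allele.copy()
    out.effect_allele[flip_arr] = out.other_allele[flip_arr]
    out.other_allele[flip_arr] = ea[flip_arr]
    return out, log


def compute_prs(
    genotypes: GenotypeMatrix,
    weights: pd.DataFrame,
    missing_policy: str = "mean",
) -> pd.DataFrame:
    """Per-sample PRS = Σₙ βₙ · dosageₙ over the harmonized SNP set.

    Parameters
    ----------
    genotypes
        Harmonized matrix (dosages count each weight's effect allele).
    weights
        Weight table; only SNPs present in the matrix contribute.
    missing_policy
        - ``"mean"`` (default): a missing dosage is replaced by twice the
          effect-allele frequency estimated from the cohort's non-missing
          calls at that SNP (mean imputation);
        - ``"drop"``: missing SNPs simply do not contribute to that sample;
        - ``"fail"``: any missing dosage raises.

    Returns
    -------
    DataFrame with ``sample_id``, ``prs``, ``n_snps_used`` and
    ``n_missing_imputed``. A sample missing every dosage has an undefined
    score (NaN) and is reported as such.
    """
    validate_weights(weights)
    wt = weights.set_index("snp_id")
    order = [s for s in wt.index if s in set(genotypes.snp_ids)]
    if not order:
        raise InvalidInputError("no overlapping snp ids between genotypes and weights")
    cols = np.array([genotypes.snp_index(s) for s in order])
    d = genotypes.dosages[:, cols]
    beta = wt.loc[order, "beta"].to_numpy(dtype=float)

    missing = np.isnan(d)
    all_missing = missing.all(axis=1)
    if missing_policy == "fail":
        if missing.any():
            raise InvalidInputError("missing dosages present under missing_policy='fail'")
        filled = d
    elif missing_policy == "drop":
        filled = np.where(missing, 0.0, d)
    elif missing_policy == "mean":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
            freq = np.nanmean(d, axis=0) / 2.0
        fill = 2.0 * freq  # expected dosage under HWE
        filled = np.where(missing, fill[None, :], d)
    else:
        raise InvalidConfigError(f"unknown missing policy {missing_policy!r}")

    prs = np.where(np.isnan(filled).any(axis=1), np.nan, np.nan_to_num(filled) @ beta)
    prs = np.where(all_missing, np.nan, prs)
    return pd.DataFrame(
        {
            "sample_id": genotypes.sample_ids,
            "prs": prs,
            "n_snps_used": (~missing).sum(axis=1),
            "n_missing_imputed": missing.sum(axis=1) if missing_policy == "mean" else 0,
        }
    )


@dataclass
class ReferenceDistribution:
    """Sorted PRS values of a reference cohort, defining the percentile map."""

    values: np.ndarray
    label: str = "reference"

    def __post_init__(self) -> None:
        self.values = np.sort(np.asarray(self.values, dtype=float))
        if self.values.size == 0:
            raise EmptyInputError("reference distribution cannot be empty")
        if np.isnan(self.values).any():
            raise InvalidInputError("reference distribution contains NaN")

    @property
    def n(self) -> int:
        return int(self.values.size)

    def summary(self) -> dict[str, float]:
        deciles = np.quantile(self.values, np.arange(0.1, 1.0, 0.1))
        out = {"min": float(self.values[0]), "max": float(self.values[-1])}
        out.update({f"d{10 * (i + 1)}": float(v) for i, v in enumerate(deciles)})
        return out


def build_reference(prs_values, label: str = "reference") -> ReferenceDistribution:
    """Sort a vector of reference-cohort scores into a percentile map."""
    values = np.asarray(prs_values, dtype=float)
    if values.size < 2:
        raise EmptyInputError("a reference distribution needs at least 2 values")
    return ReferenceDistribution(values=values, label=label)


def percentile_of(score, reference: ReferenceDistribution):
    """Empirical-CDF percentile: 100 · #{reference ≤ score} / n, in [0, 100].

    Vectorised over ``score``; ties count ("≤" convention).
    """
    score = np.asarray(score, dtype=float)
    counts = np.searchsorted(reference.values, score, side="right")
    pct = 100.0 * counts / reference.n
    return float(pct) if pct.ndim == 0 else pct
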