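"""Risk stratification: prevalence-by-percentile, ROC/AUC, cutoff, odds ratios.

Higher PRS means higher early-menopause risk throughout. Classification is
operational and percentile-based: a woman whose score percentile in the
reference distribution strictly exceeds the cutoff percentile (default 90)
is labelled high risk, everyone else intermediate risk.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as sps
from sklearn.metrics import roc_curve as _sk_roc_curve

from .errors import InvalidConfigError, InvalidInputError, UndefinedStatisticError
from .score import ReferenceDistribution, percentile_of
from .stats import OddsRatioCI, odds_ratio_woolf

__all__ = [
    "RocCurve",
    "prevalence_by_percentile",
    "roc_auc",
    "select_cutoff",
    "classify",
    "or_by_percentile_bin",
    "DEFAULT_PERCENTILE_BINS",
]

#: Fig-4B-style percentile bins (lower, upper]; (40, 60] is the reference.
DEFAULT_PERCENTILE_BINS = [
    (0, 5), (5, 10), (10, 20), (20, 40), (40, 60), (60, 80), (80, 90), (90, 95), (95, 100),
]


def _check_aligned(prs, status):
    prs = np.asarray(prs, dtype=float)
    status = np.asarray(status).astype(int)
    if prs.shape != status.shape or prs.ndim != 1:
        raise InvalidInputError("prs and status must be aligned 1-D arrays")
    if np.isnan(prs).any():
        raise InvalidInputError("prs contains NaN; resolve undefined scores first")
    if not np.isin(status, (0, 1)).all():
        raise InvalidInputError("status must be binary 0/1")
    return prs, status


def prevalence_by_percentile(prs, status, n_bins: int = 20) -> pd.DataFrame:
    """Case prevalence within equal-count percentile bins of the score.

    Samples are ranked by PRS and split into ``n_bins`` near-equal-count
    bins; each bin reports its sample count, case count and case fraction.
    """
    prs, status = _check_aligned(prs, status)
    if n_bins < 2:
        raise InvalidInputError("n_bins must be at least 2")
    if len(prs) < n_bins:
        raise InvalidInputError("fewer samples than bins")
    order = np.argsort(prs, kind="mergesort")
    chunks = np.array_split(order, n_bins)
    rows = []
    for k, idx in enumerate(chunks):
        rows.append(
            {
                "bin": k,
                "pct_low": 100.0 * k / n_bins,
                "pct_high": 100.0 * (k + 1) / n_bins,
                "n": len(idx),
                "n_cases": int(status[idx].sum()),
                "prevalence": float(status[idx].mean()),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class RocCurve:
    """ROC curve with thresholds and the rank-based AUC."""

    thresholds: np.ndarray  # decreasing; one per operating point
    tpr: np.ndarray  # sensitivity
    fpr: np.ndarray  # 1 − specificity
    auc: float

    @property
    def youden_j(self) -> np.ndarray:
        return self.tpr - self.fpr


def roc_auc(prs, status) -> RocCurve:
    """ROC curve and AUC for the score against binary case status.

    The AUC uses the rank (Mann–Whitney) formulation with tie correction:
    the probability a random case outscores a random control, ties counting
    one half. The operating points come from a full threshold sweep.
    """
    prs, status = _check_aligned(prs, status)
    n1 = int(status.sum())
    n0 = len(status) - n1
    if n1 == 0 or n0 == 0:
        raise UndefinedStatisticError("AUC undefined with a single class")
    ranks = sps.rankdata(prs)  # midranks handle ties
    auc = (ranks[status == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
    fpr, tpr, thr = _sk_roc_curve(status, prs)
    return RocCurve(thresholds=thr, tpr=tpr, fpr=fpr, auc=float(auc))


def select_cutoff(
    roc: RocCurve,
    method: str = "youden",
    reference: ReferenceDistribution | None = None,
) -> tuple[float, float | None]:
    """Pick a score cutoff from the ROC curve.

    ``"youden"`` maximises J = sensitivity + specificity − 1; ties are broken
    toward the higher-specificity (hence higher-threshold) operating point.
    Returns ``(cutoff_value, cutoff_percentile)``; the percentile is the
    cutoff's empirical percentile in ``reference`` (None when no reference
    is given).
    """
    if method != "youden":
        raise InvalidConfigError(f"unknown cutoff method {method!r}")
    j = roc.youden_j
    finite = np.isfinite(roc.thresholds)
    j_max = j[finite].max()
    candidates = np.flatnonzero(finite & (j >= j_max - 1e-12))
    # thresholds are sorted decreasing, so the first candidate has the
    # lowest fpr (highest specificity) and the highest threshold
    best = candidates[0]
    cutoff = float(roc.thresholds[best])
    pct = percentile_of(cutoff, reference) if reference is not None else None
    return cutoff, pct


def classify(
    prs_results: pd.DataFrame,
    reference: ReferenceDistribution,
    cutoff_percentile: float = 90.0,
) -> pd.DataFrame:
    """Label samples high/intermediate risk by reference percentile.

    A sample is ``high`` iff its percentile strictly exceeds
    ``cutoff_percentile``; a percentile exactly at the cutoff stays
    ``intermediate``. Input needs ``sample_id`` and ``prs`` columns (NaN
    scores get a NaN percentile and no label).
    """
    prs = prs_results["prs"].to_numpy(dtype=float)
    pct = np.full(len(prs), np.nan)
    ok = ~np.isnan(prs)
    pct[ok] = percentile_of(prs[ok], reference)
    label = np.where(np.isnan(pct), None, np.where(pct > cutoff_percentile, "high", "intermediate"))
    return pd.DataFrame(
        {
            "sample_id": prs_results["sample_id"].to_numpy(),
            "prs": prs,
            "percentile": pct,
            "label": label,
            "cutoff_percentile": cutoff_percentile,
        }
    )


def or_by_percentile_bin(
    prs,
    status,
    bins: list[tuple[float, float]] | None = None,
    reference_bin: tuple[float, float] = (40, 60),
    reference: ReferenceDistribution | None = None,
) -> pd.DataFrame:
    """Odds ratio of case status per percentile bin versus a reference bin.

    Each bin ``(lo, hi]`` collects samples whose percentile (by default in
    the analyzed cohort's own empirical distribution) satisfies
    ``lo < pct ≤ hi``. For every bin a 2×2 table against the reference bin
    (default the average-risk 40–60% band) gives an odds ratio with a Woolf
    95% CI; any zero cell is handled by the Haldane–Anscombe 0.5 correction
    and flagged.
    """
    prs, status = _check_aligned(prs, status)
    if bins is None:
        bins = DEFAULT_PERCENTILE_BINS
    ref = reference if reference is not None else ReferenceDistribution(prs, label="self")
    pct = percentile_of(prs, ref)

    def bin_counts(lo, hi):
        mask = (pct > lo) & (pct <= hi)
        return int(status[mask].sum()), int((~status.astype(bool))[mask].sum())

    ref_cases, ref_ctrls = bin_counts(*reference_bin)
    if ref_cases == 0 or ref_ctrls == 0:
        raise InvalidInputError("reference bin must contain both cases and controls")
    rows = []
    for lo, hi in bins:
        cases, ctrls = bin_counts(lo, hi)
        is_ref = (lo, hi) == tuple(reference_bin)
        if is_ref:
            effect = OddsRatioCI(1.0, 1.0, 1.0)
        else:
            effect = odds_ratio_woolf([[cases, ctrls], [ref_cases, ref_ctrls]])
        rows.append(
            {
                "pct_low": lo,
                "pct_high": hi,
                "n_cases": cases,
                "n_controls": ctrls,
                "odds_ratio": effect.odds_ratio,
                "ci_low": effect.ci_low,
                "ci_high": effect.ci_high,
                "zero_cell_corrected": effect.continuity_corrected,
                "is_reference": is_ref,
            }
        )
    return pd.DataFrame(rows)
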