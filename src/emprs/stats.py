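"""Contingency-table and two-sample statistics for the group-comparison report.

Implements the toolkit used to compare risk groups: Pearson's chi-square
(no continuity correction), Fisher's exact test for 2×2 tables, the
Freeman–Halton exact test for r×c tables, Woolf (logit) confidence intervals
for odds ratios, the classical pooled-variance two-sample t-test, and an
automatic test-selection rule (exact test whenever any expected cell count
falls below 5).

Two-sided exact p-values follow the "probability at most that of the observed
table" convention throughout, with the margins held fixed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from math import lgamma

import numpy as np
import pandas as pd
import scipy.stats as sps

from .errors import (
    DegenerateTableError,
    InvalidConfigError,
    InvalidInputError,
    ResourceLimitError,
)

__all__ = [
    "ContingencyTable",
    "TestResult",
    "OddsRatioCI",
    "pearson_chi2",
    "fisher_exact_2x2",
    "freeman_halton",
    "odds_ratio_woolf",
    "student_t",
    "student_t_from_samples",
    "compare_groups",
    "format_report_markdown",
]

# Relative tolerance when comparing table probabilities to the observed one,
# so float noise cannot split exact ties (same convention scipy uses).
_REL_TOL = 1e-7


@dataclass
class ContingencyTable:
    """r×c table of non-negative integer counts with optional labels."""

    counts: np.ndarray
    row_labels: list[str] | None = None
    col_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or min(self.counts.shape) < 2:
            raise InvalidInputError("contingency table must be at least 2×2")
        if (self.counts < 0).any() or not np.issubdtype(self.counts.dtype, np.integer):
            as_int = np.asarray(self.counts, dtype=float)
            if (as_int < 0).any() or not np.allclose(as_int, np.round(as_int)):
                raise InvalidInputError("counts must be non-negative integers")
            self.counts = np.round(as_int).astype(int)
        if self.row_labels is None:
            self.row_labels = [f"row{i}" for i in range(self.counts.shape[0])]
        if self.col_labels is None:
            self.col_labels = [f"col{j}" for j in range(self.counts.shape[1])]


@dataclass
class OddsRatioCI:
    """Odds ratio with a Woolf 95% confidence interval."""

    odds_ratio: float
    ci_low: float
    ci_high: float
    continuity_corrected: bool = False

    def __iter__(self):
        return iter((self.odds_ratio, self.ci_low, self.ci_high))


@dataclass
class TestResult:
    """Outcome of a single statistical test."""

    test_name: str
    p_value: float
    statistic: float | None = None
    df: int | None = None
    effect: OddsRatioCI | None = None
    notes: list[str] = field(default_factory=list)


def _as_counts(table) -> np.ndarray:
    if isinstance(table, ContingencyTable):
        return table.counts
    return ContingencyTable(np.asarray(table)).counts


# ---------------------------------------------------------------------------
# Pearson chi-square


def pearson_chi2(table) -> TestResult:
    """Pearson chi-square test of independence, without continuity correction.

    ``χ² = Σ (O − E)² / E`` with ``df = (r−1)(c−1)``; the p-value comes from
    the chi-square distribution. A zero row or column margin makes the
    expected counts undefined and raises :class:`DegenerateTableError`.
    """
    counts = _as_counts(table)
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise DegenerateTableError("zero margin: expected counts undefined")
    stat, p, df, _ = sps.chi2_contingency(counts, correction=False)
    return TestResult(test_name="pearson_chi2", statistic=float(stat), df=int(df), p_value=float(p))


# ---------------------------------------------------------------------------
# Exact tests


def fisher_exact_2x2(table) -> TestResult:
    """Two-sided Fisher exact test for a 2×2 table.

    Sums hypergeometric probabilities (margins fixed) of every table at most
    as probable as the observed one.
    """
    counts = _as_counts(table)
    if counts.shape != (2, 2):
        raise InvalidInputError("fisher_exact_2x2 requires a 2×2 table")
    _, p = sps.fisher_exact(counts, alternative="two-sided")
    result = TestResult(test_name="fisher_exact", statistic=None, p_value=float(min(p, 1.0)))
    if counts.sum() > 0 and not ((counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any()):
        try:
            result.effect = odds_ratio_woolf(counts)
        except DegenerateTableError:
            pass
    return result


def _log_table_prob(counts: np.ndarray, row: np.ndarray, col: np.ndarray, n: int) -> float:
    """Log multivariate-hypergeometric probability of a table given its margins."""
    lp = sum(lgamma(r + 1) for r in row) + sum(lgamma(c + 1) for c in col) - lgamma(n + 1)
    lp -= sum(lgamma(int(x) + 1) for x in counts.flat)
    return lp


def _enumerate_tables(row: np.ndarray, col: np.ndarray):
    """Yield every non-negative integer table with the given margins.

    Depth-first over cells in row-major order; the last cell of each row and
    the whole last row are forced by the margins.
    """
    r, c = len(row), len(col)
    table = np.zeros((r, c), dtype=int)
    col_left = col.copy()

    def rec_row(i: int):
        if i == r - 1:
            if (col_left >= 0).all():
                table[i] = col_left
                yield table
            return
        yield from rec_cell(i, 0, int(row[i]))

    def rec_cell(i: int, j: int, row_left: int):
        if j == c - 1:
            if 0 <= row_left <= col_left[j]:
                table[i, j] = row_left
                col_left[j] -= row_left
                yield from rec_row(i + 1)
                col_left[j] += row_left
            return
        hi = min(row_left, int(col_left[j]))
        for v in range(hi + 1):
            table[i, j] = v
            col_left[j] -= v
            yield from rec_cell(i, j + 1, row_left - v)
            col_left[j] += v

    yield from rec_row(0)


def _enumeration_size_bound(row: np.ndarray, c: int) -> float:
    """Upper bound on the number of margin-compatible tables."""
    return float(np.prod([math.comb(int(r) + c - 1, c - 1) for r in row[:-1]]))


def freeman_halton(
    table,
    *,
    max_total: int = 500,
    max_tables: float = 5e6,
    method: str = "exact",
    n_monte_carlo: int = 100_000,
    seed: int | None = None,
) -> TestResult:
    """Freeman–Halton exact test of independence for an r×c table.

    Generalises Fisher's exact test: with all margins fixed, the two-sided
    p-value sums the multivariate-hypergeometric probabilities of every table
    whose probability does not exceed the observed table's.

    Parameters
    ----------
    max_total, max_tables
        Enumeration guards. Tables with ``N > max_total`` or more candidate
        tables than ``max_tables`` raise :class:`ResourceLimitError` advising
        ``method="monte-carlo"``.
    method
        ``"exact"`` (default) or ``"monte-carlo"`` (margin-preserving table
        sampling via :func:`scipy.stats.random_table`; requires ``seed``).
    """
    counts = _as_counts(table)
    row, col = counts.sum(axis=1), counts.sum(axis=0)
    n = int(counts.sum())
    if n == 0:
        raise DegenerateTableError("empty table")
    keep_r, keep_c = row > 0, col > 0
    if keep_r.sum() < 2 or keep_c.sum() < 2:
        # only one populated line: independence holds trivially
        return TestResult(test_name="freeman_halton", statistic=None, p_value=1.0,
                          notes=["degenerate margins; p = 1"])
    counts = counts[np.ix_(keep_r, keep_c)]
    row, col = counts.sum(axis=1), counts.sum(axis=0)

    log_obs = _log_table_prob(counts, row, col, n)
    if method == "monte-carlo":
        if seed is None:
            raise InvalidConfigError("monte-carlo mode requires a seed")
        rng = np.random.default_rng(seed)
        dist = sps.random_table(row, col)
        hits = 0
        for chunk in range(0, n_monte_carlo, 10_000):
            k = min(10_000, n_monte_carlo - chunk)
            samples = dist.rvs(size=k, random_state=rng)
            lps = np.array([_log_table_prob(t, row, col, n) for t in samples])
            hits += int((lps <= log_obs + _REL_TOL).sum())
        # add-one estimator keeps the p-value positive
        p = (hits + 1) / (n_monte_carlo + 1)
        return TestResult(test_name="freeman_halton", statistic=None, p_value=float(p),
                          notes=[f"monte-carlo p with {n_monte_carlo} tables"])
    if method != "exact":
        raise InvalidConfigError(f"unknown method {method!r}")
    if n > max_total or _enumeration_size_bound(row, len(col)) > max_tables:
        raise ResourceLimitError(
            f"table total {n} exceeds the exact enumeration guard; "
            "re-run with method='monte-carlo' and a seed"
        )
    p = 0.0
    for t in _enumerate_tables(row, col):
        lp = _log_table_prob(t, row, col, n)
        if lp <= log_obs + _REL_TOL:
            p += math.exp(lp)
    return TestResult(test_name="freeman_halton", statistic=None, p_value=float(min(p, 1.0)))


# ---------------------------------------------------------------------------
# Odds ratio


def odds_ratio_woolf(table, *, z: float = 1.96) -> OddsRatioCI:
    """Odds ratio with a Woolf (logit) confidence interval.

    ``OR = ad/bc``; ``CI = exp(ln OR ± z·√(1/a + 1/b + 1/c + 1/d))``.
    Any single zero cell triggers the Haldane–Anscombe correction (0.5 added
    to every cell, flagged on the result); a fully zero row or column leaves
    the OR undefined and raises.
    """
    counts = _as_counts(table).astype(float)
    if counts.shape != (2, 2):
        raise InvalidInputError("odds ratio requires a 2×2 table")
    if (counts.sum(axis=1) == 0).any() or (counts.sum(axis=0) == 0).any():
        raise DegenerateTableError("a zero row/column leaves the odds ratio undefined")
    corrected = False
    if (counts == 0).any():
        counts = counts + 0.5
        corrected = True
    a, b = counts[0]
    c, d = counts[1]
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return OddsRatioCI(
        odds_ratio=or_,
        ci_low=or_ * math.exp(-z * se),
        ci_high=or_ * math.exp(z * se),
        continuity_corrected=corrected,
    )


# ---------------------------------------------------------------------------
# Two-sample t


def student_t(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int, *, welch: bool = False
) -> TestResult:
    """Two-sided two-sample t-test from group summaries.

    Classical pooled-variance Student's t by default
    (``df = n1 + n2 − 2``); ``welch=True`` switches to the
    Welch–Satterthwaite unequal-variance form.
    """
    if n1 < 2 or n2 < 2:
        raise InvalidInputError("each group needs at least 2 observations")
    if sd1 <= 0 or sd2 <= 0:
        raise InvalidInputError("standard deviations must be positive")
    if welch:
        v1, v2 = sd1**2 / n1, sd2**2 / n2
        t = (mean1 - mean2) / math.sqrt(v1 + v2)
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
        name = "welch_t"
    else:
        sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2)
        t = (mean1 - mean2) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
        df = n1 + n2 - 2
        name = "student_t"
    p = 2.0 * sps.t.sf(abs(t), df)
    return TestResult(test_name=name, statistic=float(t), df=int(round(df)), p_value=float(p))


def student_t_from_samples(x1, x2, *, welch: bool = False) -> TestResult:
    """Raw-data overload of :func:`student_t` (sample SDs use ddof=1)."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    x1, x2 = x1[~np.isnan(x1)], x2[~np.isnan(x2)]
    if len(x1) < 2 or len(x2) < 2:
        raise InvalidInputError("each group needs at least 2 observations")
    return student_t(
        x1.mean(), x1.std(ddof=1), len(x1), x2.mean(), x2.std(ddof=1), len(x2), welch=welch
    )


# ---------------------------------------------------------------------------
# Group-comparison report


def _select_categorical_test(counts: np.ndarray) -> TestResult:
    """Chi-square unless any expected cell is below 5, then the exact test."""
    expected = sps.contingency.expected_freq(counts)
    if (expected < 5).any():
        if counts.shape == (2, 2):
            return fisher_exact_2x2(counts)
        return freeman_halton(counts)
    return pearson_chi2(counts)


def compare_groups(
    cohort: pd.DataFrame,
    group_label: str,
    variables: dict[str, str],
    *,
    group_order: list | None = None,
) -> pd.DataFrame:
    """Compare every variable between the two groups, publication-table style.

    Continuous variables get the pooled two-sample t-test; categorical
    variables get Pearson's chi-square unless any expected cell count is
    below 5, in which case the exact test (Fisher for 2×2, Freeman–Halton
    otherwise) is selected automatically. Records with a missing value for a
    variable (non-applicable items) are dropped pairwise for that variable
    only.

    Parameters
    ----------
    cohort
        One row per participant.
    group_label
        Binary grouping column (e.g. the high/intermediate risk label).
    variables
        Mapping of column name to ``"continuous"`` or ``"categorical"``.
    group_order
        Optional explicit order of the two group levels; defaults to
        ``["high", ...]`` first when present, else sorted.

    Returns
    -------
    DataFrame with one row per variable (and per level for categorical
    variables): descriptive summaries per group, the test used, the statistic
    and the p-value. Variables with a single observed level are skipped with
    a note.
    """
    groups = [g for g in pd.unique(cohort[group_label].dropna())]
    if len(groups) != 2:
        raise InvalidInputError(f"group column {group_label!r} must have exactly 2 levels")
    if group_order is not None:
        groups = list(group_order)
    elif "high" in groups:
        groups = ["high"] + [g for g in groups if g != "high"]
    else:
        groups = sorted(groups)

    rows: list[dict] = []
    for var, kind in variables.items():
        sub = cohort[[group_label, var]].dropna()
        g1 = sub.loc[sub[group_label] == groups[0], var]
        g2 = sub.loc[sub[group_label] == groups[1], var]
        if kind == "continuous":
            try:
                res = student_t_from_samples(g1, g2)
            except InvalidInputError as exc:
                rows.append({"variable": var, "level": "", "note": str(exc)})
                continue
            rows.append(
                {
                    "variable": var,
                    "level": "",
                    "kind": "continuous",
                    "n": len(sub),
                    f"summary_{groups[0]}": f"{g1.mean():.2f} ± {g1.std(ddof=1):.2f}",
                    f"summary_{groups[1]}": f"{g2.mean():.2f} ± {g2.std(ddof=1):.2f}",
                    "test": res.test_name,
                    "statistic": res.statistic,
                    "p_value": res.p_value,
                }
            )
        elif kind == "categorical":
            levels = list(pd.unique(sub[var]))
            if sub[var].dtype != object:
                levels = sorted(levels)
            if len(levels) < 2:
                rows.append({"variable": var, "level": "", "note": "single observed level; skipped"})
                continue
            counts = np.array(
                [[int(((sub[group_label] == g) & (sub[var] == lv)).sum()) for g in groups]
                 for lv in levels]
            )
            res = _select_categorical_test(counts)
            for i, lv in enumerate(levels):
                n1, n2 = counts[i]
                tot1, tot2 = counts.sum(axis=0)
                rows.append(
                    {
                        "variable": var,
                        "level": str(lv),
                        "kind": "categorical",
                        "n": len(sub),
                        f"summary_{groups[0]}": f"{n1} ({100 * n1 / tot1:.2f}%)",
                        f"summary_{groups[1]}": f"{n2} ({100 * n2 / tot2:.2f}%)",
                        "test": res.test_name if i == 0 else "",
                        "statistic": res.statistic if i == 0 else None,
                        "p_value": res.p_value if i == 0 else None,
                    }
                )
        else:
            raise InvalidConfigError(f"unknown variable kind {kind!r} for {var!r}")
    return pd.DataFrame(rows)


def _format_p(p: float | None) -> str:
    if p is None or (isinstance(p, float) and math.isnan(p)):
        return ""
    return "<.001" if p < 0.001 else f"{p:.3f}"


def _format_stat(test: str, stat: float | None) -> str:
    if not test:
        return ""
    if stat is None:
        return "–"  # exact test: no statistic, the tables' dialect
    prefix = {"pearson_chi2": "χ²=", "student_t": "t=", "welch_t": "t="}.get(test, "")
    return f"{prefix}{stat:.2f}"


def format_report_markdown(report: pd.DataFrame, title: str = "Group comparison") -> str:
    """Render a :func:`compare_groups` report as a Markdown table."""
    summary_cols = [c for c in report.columns if c.startswith("summary_")]
    header = ["Variable", "Level"] + [c.removeprefix("summary_") for c in summary_cols]
    header += ["Statistic", "P"]
    lines = [f"## {title}", "", "| " + " | ".join(header) + " |",
             "|" + "---|" * len(header)]
    for _, r in report.iterrows():
        stat = _format_stat(r.get("test", ""), r.get("statistic"))
        p = _format_p(r.get("p_value"))
        cells = [str(r["variable"]), str(r.get("level", ""))]
        cells += [str(r.get(c, "") or "") for c in summary_cols]
        cells += [stat, p]
        lines.append("| " + " | ".join(cells) + " |")
    return "\n".join(lines) + "\n"
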