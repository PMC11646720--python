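"""Independent brute-force oracles used to cross-check the implementations.

These deliberately share no code with the package: exact-test p-values come
from direct enumeration with integer arithmetic (ties resolved by exact
integer comparison), and the AUC oracle is the naive double loop over
case-control pairs.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb, factorial

import numpy as np


def fisher_2x2_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by full hypergeometric enumeration.

    Integer weights C(r0, x)·C(r1, col0 − x) make tie comparison exact.
    """
    r0, r1 = a + b, c + d
    col0 = a + c
    lo, hi = max(0, col0 - r1), min(r0, col0)
    w_obs = comb(r0, a) * comb(r1, col0 - a)
    num = sum(
        comb(r0, x) * comb(r1, col0 - x)
        for x in range(lo, hi + 1)
        if comb(r0, x) * comb(r1, col0 - x) <= w_obs
    )
    return float(Fraction(num, comb(r0 + r1, col0)))


def rxc_exact_oracle(table) -> float:
    """Freeman–Halton p by exhaustive enumeration with exact rationals.

    Enumerates the first r−1 rows cell-by-cell with itertools products of
    candidate row fillings; infeasible cells are skipped by margin checks.
    """
    table = np.asarray(table, dtype=int)
    row, col = table.sum(axis=1), table.sum(axis=0)
    n = int(table.sum())

    def weight(t) -> Fraction:
        # P(T) * N! / (prod r_i! prod c_j!) inverse cells -> use integer weight
        denom = 1
        for x in np.asarray(t).flat:
            denom *= factorial(int(x))
        return Fraction(1, denom)

    w_obs = weight(table)
    total = Fraction(0)
    hits = Fraction(0)
    r, c = table.shape

    def row_fillings(total_row, col_left):
        """All ways to fill one row given its sum and remaining column room."""
        ranges = [range(min(total_row, int(cl)) + 1) for cl in col_left[:-1]]
        for cells in itertools.product(*ranges):
            last = total_row - sum(cells)
            if 0 <= last <= col_left[-1]:
                yield cells + (last,)

    def rec(i, col_left, acc):
        nonlocal total, hits
        if i == r - 1:
            t = acc + [tuple(col_left)]
            w = weight(t)
            total += w
            if w <= w_obs:
                hits += w
            return
        for filling in row_fillings(int(row[i]), col_left):
            rec(i + 1, col_left - np.array(filling), acc + [filling])

    rec(0, col.copy(), [])
    return float(hits / total)


def hwe_oracle(n_hom_a: int, n_het: int, n_hom_b: int) -> float:
    """Exact HWE p by enumeration of heterozygote counts, exact rationals."""
    n = n_hom_a + n_het + n_hom_b
    n_a = 2 * n_hom_a + n_het
    weights = {}
    for het in range(min(n_a, 2 * n - n_a) + 1):
        if (n_a - het) % 2:
            continue
        homa, homb = (n_a - het) // 2, (2 * n - n_a - het) // 2
        weights[het] = Fraction(
            factorial(n) * 2**het, factorial(homa) * factorial(het) * factorial(homb)
        )
    total = sum(weights.values())
    w_obs = weights[n_het]
    return float(sum(w for w in weights.values() if w <= w_obs) / total)


def auc_pairs_oracle(scores, status) -> float:
    """AUC as (concordant + ½·tied) case-control pairs, naive double loop."""
    scores = np.asarray(scores, dtype=float)
    status = np.asarray(status, dtype=int)
    cases = scores[status == 1]
    controls = scores[status == 0]
    total = 0.0
    for x in cases:
        for y in controls:
            total += 1.0 if x > y else (0.5 if x == y else 0.0)
    return total / (len(cases) * len(controls))


def all_2x2_tables(max_total: int):
    """Every 2×2 non-negative table with 1 ≤ total ≤ max_total."""
    for n in range(1, max_total + 1):
        for a in range(n + 1):
            for b in range(n - a + 1):
                for c in range(n - a - b + 1):
                    yield a, b, c, n - a - b - c
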