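"""Independent brute-force oracles used by the test suite.

Deliberately naive (explicit Python loops, no shared code with the
package) so they can serve as a second, independent evaluation of the
same definitions.
"""

from __future__ import annotations

import math

import numpy as np


def oracle_centralize(values: list[list[float]]) -> list[list[float]]:
    """Row-wise division by the mean of non-missing cells (NaN kept)."""
    out = []
    for row in values:
        present = [v for v in row if not math.isnan(v)]
        mean = sum(present) / len(present)
        out.append([v / mean if not math.isnan(v) else float("nan") for v in row])
    return out


def oracle_fold_change(row: list[float], idx_a: list[int], idx_b: list[int]) -> float:
    """Ratio of group means of relative values for one site."""
    vals_a = [row[i] for i in idx_a if not math.isnan(row[i])]
    vals_b = [row[i] for i in idx_b if not math.isnan(row[i])]
    if not vals_a or not vals_b:
        return float("nan")
    mean_b = sum(vals_b) / len(vals_b)
    if mean_b == 0:
        return float("nan")
    return (sum(vals_a) / len(vals_a)) / mean_b


def oracle_cv(row: list[float], pairs: list[tuple[int, int]]) -> float:
    """CV (sample SD / mean) of replicate-paired ratios for one site."""
    ratios = []
    for ia, ib in pairs:
        a, b = row[ia], row[ib]
        if math.isnan(a) or math.isnan(b) or b == 0:
            continue
        ratios.append(a / b)
    if len(ratios) < 2:
        return float("nan")
    mean = sum(ratios) / len(ratios)
    var = sum((r - mean) ** 2 for r in ratios) / (len(ratios) - 1)
    return math.sqrt(var) / mean


def oracle_pls_weights(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Closed-form single-component PLS weights: w proportional to X'y."""
    yc = y - y.mean()
    w = X.T @ yc
    return w / np.linalg.norm(w)


def oracle_vip(weights: np.ndarray) -> np.ndarray:
    """VIP from a single predictive component, evaluated from scratch.

    VIP_j = sqrt( p * SSY * (w_j/||w||)^2 / SSY ) = sqrt(p) * |w_j| / ||w||.
    """
    w = np.asarray(weights, dtype=float)
    p = w.shape[0]
    norm = math.sqrt(sum(wj * wj for wj in w))
    return np.array([math.sqrt(p * (wj / norm) ** 2) for wj in w])


def oracle_hypergeom_tail(k: int, n_universe: int, n_cat: int, n_sel: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n) by exact tail summation."""
    total = 0.0
    upper = min(n_cat, n_sel)
    for x in range(k, upper + 1):
        total += (
            math.comb(n_cat, x)
            * math.comb(n_universe - n_cat, n_sel - x)
            / math.comb(n_universe, n_sel)
        )
    return min(total, 1.0)
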