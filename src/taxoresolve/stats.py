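"""The two significance tests used by the decision rules.

Both report two-sided p-values.  p-values are floored at machine epsilon
and formatted as "<1e-15" rather than 0 for display.
"""

from __future__ import annotations

import itertools
import math
import sys
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy.stats import norm

EPS = sys.float_info.epsilon

EXACT_LIMIT = 12  # combined sample size at or below which p is exact


def _u_statistic(x: Sequence[float], y: Sequence[float]) -> float:
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    gt = (xa[:, None] > ya[None, :]).sum()
    eq = (xa[:, None] == ya[None, :]).sum()
    return float(gt) + 0.5 * float(eq)


def mann_whitney_u(x: Sequence[float], y: Sequence[float],
                   mode: str = "auto") -> tuple[float, float]:
    """Mann-Whitney U with a two-sided p-value.

    U counts pairs with x_i > y_j plus half the ties.  The p-value is
    computed by exhaustive enumeration of rank splits when
    len(x)+len(y) <= 12 (or mode="exact"), otherwise by the normal
    approximation with tie and continuity corrections.
    """
    if len(x) == 0 or len(y) == 0:
        raise ValueError("empty sample")
    if mode not in ("auto", "exact", "normal"):
        raise ValueError(f"unknown mode {mode!r}")
    nx, ny = len(x), len(y)
    u = _u_statistic(x, y)
    if mode == "exact" or (mode == "auto" and nx + ny <= EXACT_LIMIT):
        pooled = list(x) + list(y)
        if len(set(pooled)) == len(pooled) and nx * ny <= 40_000:
            p = _exact_p_no_ties(nx, ny, u)
        elif nx + ny <= EXACT_LIMIT:
            p = _exact_p(x, y, u)
        elif mode == "exact":
            raise ValueError(
                "exact mode with tied data is limited to combined sample "
                f"sizes <= {EXACT_LIMIT}")
        else:
            p = _normal_p(x, y, u)
    else:
        p = _normal_p(x, y, u)
    return u, max(p, EPS)


@lru_cache(maxsize=4096)
def _u_null_counts(m: int, n: int) -> "np.ndarray":
    """Null distribution counts of U over all C(m+n, m) rank splits."""
    if m == 0 or n == 0:
        return np.ones(1)
    a = _u_null_counts(m - 1, n)
    b = _u_null_counts(m, n - 1)
    out = np.zeros(m * n + 1)
    out[n:n + a.size] += a
    out[:b.size] += b
    return out


def _exact_p_no_ties(nx: int, ny: int, u_obs: float) -> float:
    counts = _u_null_counts(nx, ny)
    total = counts.sum()
    u = int(round(u_obs))
    lo = counts[:u + 1].sum() / total
    hi = counts[u:].sum() / total
    return min(1.0, 2.0 * min(lo, hi))


def _exact_p(x, y, u_obs: float) -> float:
    pooled = sorted(list(x) + list(y))
    nx = len(x)
    n = len(pooled)
    lo = 0
    hi = 0
    total = 0
    for idx in itertools.combinations(range(n), nx):
        chosen = set(idx)
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(n) if i not in chosen]
        u = _u_statistic(xs, ys)
        total += 1
        if u <= u_obs + 1e-12:
            lo += 1
        if u >= u_obs - 1e-12:
            hi += 1
    p = 2.0 * min(lo, hi) / total
    return min(p, 1.0)


def _normal_p(x, y, u: float) -> float:
    nx, ny = len(x), len(y)
    n = nx + ny
    pooled = np.concatenate([np.asarray(x, float), np.asarray(y, float)])
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = ((counts ** 3 - counts).sum()) / (n * (n - 1))
    mean_u = nx * ny / 2.0
    var_u = nx * ny / 12.0 * ((n + 1) - tie_term)
    if var_u <= 0:
        return 1.0
    # Continuity correction toward the mean.
    diff = u - mean_u
    if diff > 0.5:
        diff -= 0.5
    elif diff < -0.5:
        diff += 0.5
    else:
        diff = 0.0
    z = diff / math.sqrt(var_u)
    return float(2.0 * norm.sf(abs(z)))


def two_proportion_z(k1: int, n1: int, k2: int, n2: int) -> tuple[float, float]:
    """Pooled-variance two-proportion z test, two-sided."""
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be positive")
    if not (0 <= k1 <= n1) or not (0 <= k2 <= n2):
        raise ValueError("counts outside [0, n]")
    p1 = k1 / n1
    p2 = k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    denom = pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2)
    if denom == 0:
        return 0.0, 1.0
    z = (p1 - p2) / math.sqrt(denom)
    p = float(2.0 * norm.sf(abs(z)))
    return z, max(p, EPS)


def format_p(p: float) -> str:
    if p < 1e-15:
        return "<1e-15"
    return f"{p:.3g}"
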