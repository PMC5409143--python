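"""Spearman rank correlation from first principles.

The Spearman coefficient is defined here the tie-correct way: assign
midranks (tied values share the mean of the integer ranks they occupy)
and compute the Pearson product-moment correlation of the two midrank
vectors.  The popular 1 - 6*sum(d^2)/(n^3-n) shortcut is *not* used
because it is biased in the presence of ties.

Two p-value routes are provided and dispatched on sample size:

* exact  -- full enumeration of all n! permutations of one variable,
  two-sided tail count of |rho|; valid for any n but only practical for
  small n (default cutoff 8, i.e. 40,320 permutations).
* asymptotic -- t = rho * sqrt((n-2)/(1-rho^2)) referred to Student's t
  with n-2 degrees of freedom.

Both are two-sided: positive (resistance) and negative (sensitizing)
expression/IC50 correlations are equally interesting findings.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Literal, Sequence

import numpy as np
from scipy import stats as _scipy_stats

__all__ = [
    "CorrelationResult",
    "midrank",
    "spearman_rho",
    "spearman_p_exact",
    "spearman_p_asymptotic",
    "spearman_test",
    "DEFAULT_EXACT_THRESHOLD",
]

#: Largest n for which the exact permutation p-value is computed by default.
DEFAULT_EXACT_THRESHOLD = 8

#: Tolerance absorbing float rounding when counting tail permutations.
_EXACT_EPS = 1e-12

#: Smallest p reported when |rho| == 1 under the asymptotic route (t -> inf).
_MIN_ASYMPTOTIC_P = 5e-324


@dataclass(frozen=True)
class CorrelationResult:
    """Outcome of one Spearman test.

    rho is NaN when ``degenerate`` (either variable constant); p is then 1
    by convention so degenerate pairs can never pass a significance filter.
    """

    rho: float
    p_value: float
    n: int
    method: Literal["exact", "asymptotic", "degenerate"]
    degenerate: bool = False


def midrank(values: Sequence[float]) -> np.ndarray:
    """Midranks of ``values``: ties get the mean of the ranks they occupy.

    The output always sums to n(n+1)/2.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size < 1:
        raise ValueError("midrank expects a non-empty 1-D sequence")
    if not np.all(np.isfinite(arr)):
        raise ValueError("midrank requires finite values")
    order = np.argsort(arr, kind="stable")
    ranks = np.empty(arr.size, dtype=float)
    sorted_vals = arr[order]
    i = 0
    while i < arr.size:
        j = i
        while j + 1 < arr.size and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        # positions i..j (0-based) hold a tie block -> mean of ranks i+1..j+1
        ranks[order[i : j + 1]] = (i + j + 2) / 2.0
        i = j + 1
    return ranks


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    ca = a - a.mean()
    cb = b - b.mean()
    denom = math.sqrt(float(ca @ ca) * float(cb @ cb))
    if denom == 0.0:
        return math.nan
    return float(np.clip((ca @ cb) / denom, -1.0, 1.0))


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman correlation: Pearson on midranks. NaN if a variable is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need n >= 3 observations")
    return _pearson(midrank(x), midrank(y))


@lru_cache(maxsize=None)
def _perm_index_matrix(n: int) -> np.ndarray:
    """All n! permutations of range(n) as an (n!, n) index matrix (n <= 8)."""
    return np.array(list(itertools.permutations(range(n))), dtype=np.int8)


def spearman_p_exact(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided exact permutation p-value by full n! enumeration.

    p = #{pi : |rho(x, pi(y))| >= |rho(x, y)| - eps} / n!.  The identity
    permutation is always in the tail, so p > 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n > DEFAULT_EXACT_THRESHOLD:
        raise ValueError(
            f"exact enumeration limited to n <= {DEFAULT_EXACT_THRESHOLD}, got {n}"
        )
    rx = midrank(x)
    ry = midrank(y)
    cx = rx - rx.mean()
    cy = ry - ry.mean()
    sx = math.sqrt(float(cx @ cx))
    sy = math.sqrt(float(cy @ cy))
    if sx == 0.0 or sy == 0.0:
        raise ValueError("degenerate (constant) variable has no exact p-value")
    rho_obs = abs(float(cx @ cy) / (sx * sy))
    perms = _perm_index_matrix(n)
    # permuting y permutes its midranks; centering and scale are invariant
    rho_perm = np.abs((cy[perms] @ cx) / (sx * sy))
    count = int(np.count_nonzero(rho_perm >= rho_obs - _EXACT_EPS))
    return count / math.factorial(n)


def spearman_p_asymptotic(rho: float, n: int) -> float:
    """Two-sided p from the Student-t approximation with n-2 df."""
    if n < 4:
        raise ValueError("asymptotic approximation requires n >= 4")
    if not -1.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [-1, 1]")
    if abs(rho) == 1.0:
        return _MIN_ASYMPTOTIC_P
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    p = 2.0 * float(_scipy_stats.t.sf(abs(t), df=n - 2))
    return min(max(p, _MIN_ASYMPTOTIC_P), 1.0)


def spearman_test(
    x: Sequence[float],
    y: Sequence[float],
    exact_threshold: int = DEFAULT_EXACT_THRESHOLD,
) -> CorrelationResult:
    """Full Spearman test with automatic exact/asymptotic dispatch.

    Degenerate inputs (constant x or y) yield rho=NaN, p=1, method
    "degenerate" rather than an exception: the association engine records
    and skips them.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = int(x.size)
    if n < 3:
        raise ValueError("need n >= 3 observations")
    exact_threshold = min(int(exact_threshold), DEFAULT_EXACT_THRESHOLD)
    rho = spearman_rho(x, y)
    if math.isnan(rho):
        return CorrelationResult(math.nan, 1.0, n, "degenerate", degenerate=True)
    if n <= exact_threshold:
        return CorrelationResult(rho, spearman_p_exact(x, y), n, "exact")
    return CorrelationResult(rho, spearman_p_asymptotic(rho, n), n, "asymptotic")
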