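"""Nonparametric statistics shared across the pipeline.

Thin, contract-enforcing wrappers over scipy.stats (Spearman rank
correlation, Shapiro–Wilk, Wilcoxon signed-rank), plus the first-order
partial Spearman correlation (Pearson partial computed on ranks) and a
seeded 95% percentile bootstrap.  All randomness takes an explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    n: int


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    n: int
    p_value: float
    partial_rho: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    n_bootstrap: int | None = None


def _as_finite(x: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"non-finite values in {name}")
    return arr


def _check_not_constant(arr: np.ndarray, name: str) -> None:
    if np.all(arr == arr[0]):
        raise ValueError(f"zero rank variance: {name} is constant")


def spearman(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Spearman rank correlation with average ranks for ties and the
    t-approximation p-value."""
    xa, ya = _as_finite(x, "x"), _as_finite(y, "y")
    if len(xa) != len(ya):
        raise ValueError("x and y must have equal length")
    if len(xa) < 3:
        raise ValueError("need at least 3 observations")
    _check_not_constant(xa, "x")
    _check_not_constant(ya, "y")
    rho, p = sps.spearmanr(xa, ya)
    return CorrelationResult(rho=float(rho), n=len(xa), p_value=float(p))


def _spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    return float(sps.spearmanr(x, y).statistic)


def partial_spearman(
    x: Sequence[float], y: Sequence[float], z: Sequence[float]
) -> CorrelationResult:
    """First-order partial Spearman correlation of x and y given z:

        ρ_xy·z = (ρ_xy − ρ_xz ρ_yz) / sqrt((1 − ρ_xz²)(1 − ρ_yz²))

    with each ρ a Spearman coefficient; the p-value uses the t-approximation
    with n − 3 degrees of freedom.
    """
    xa, ya, za = _as_finite(x, "x"), _as_finite(y, "y"), _as_finite(z, "z")
    if not len(xa) == len(ya) == len(za):
        raise ValueError("x, y, z must have equal length")
    if len(xa) < 4:
        raise ValueError("need at least 4 observations")
    for arr, name in ((xa, "x"), (ya, "y"), (za, "z")):
        _check_not_constant(arr, name)
    r_xy = _spearman_rho(xa, ya)
    r_xz = _spearman_rho(xa, za)
    r_yz = _spearman_rho(ya, za)
    denom = (1.0 - r_xz**2) * (1.0 - r_yz**2)
    if denom <= 1e-12:
        raise ValueError("degenerate confounder: |rho_xz| or |rho_yz| is 1")
    pr = (r_xy - r_xz * r_yz) / np.sqrt(denom)
    pr = float(np.clip(pr, -1.0, 1.0))
    n = len(xa)
    df = n - 3
    if abs(pr) >= 1.0:
        p = 0.0
    else:
        t = pr * np.sqrt(df / (1.0 - pr**2))
        p = float(2.0 * sps.t.sf(abs(t), df))
    return CorrelationResult(rho=r_xy, n=n, p_value=p, partial_rho=pr)


def wilcoxon_signed_rank(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Paired Wilcoxon signed-rank test; zero differences dropped, exact null
    distribution up to n = 25, normal approximation with continuity
    correction beyond."""
    xa, ya = _as_finite(x, "x"), _as_finite(y, "y")
    if len(xa) != len(ya):
        raise ValueError("paired vectors must have equal length")
    d = xa - ya
    d = d[d != 0.0]
    if len(d) < 2:
        raise ValueError("fewer than 2 nonzero differences")
    method = "exact" if len(d) <= 25 else "approx"
    res = sps.wilcoxon(d, zero_method="wilcox", correction=(method == "approx"), method=method)
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue), n=len(d))


def shapiro_wilk(x: Sequence[float]) -> TestResult:
    """Shapiro–Wilk normality test (3 ≤ n ≤ 5000)."""
    xa = _as_finite(x, "x")
    if not 3 <= len(xa) <= 5000:
        raise ValueError("Shapiro–Wilk requires 3 <= n <= 5000")
    _check_not_constant(xa, "x")
    res = sps.shapiro(xa)
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue), n=len(xa))


def bootstrap_ci(
    statistic: Callable[[np.ndarray], float],
    data: Sequence[float] | np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Seeded 95% (by default) percentile bootstrap over rows of ``data``.

    ``data`` may be 1-D (a sample) or 2-D (rows = observations); the
    statistic receives the resampled array.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    arr = np.asarray(data)
    rng = np.random.default_rng(seed)
    n = arr.shape[0]
    reps = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            reps[b] = statistic(arr[idx])
        except Exception as exc:
            raise RuntimeError(f"statistic failed on resample {b}: {exc}") from exc
    lo, hi = np.quantile(reps, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi)
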