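"""Change-point, trend, and distribution-shift statistics for annual series.

Implements the nonparametric battery used to characterize the dry-to-wet
moisture regime shift: the Pettitt change-point test, the Mann-Kendall
trend test with tie correction and continuity correction, the Theil-Sen
slope, and the two-sample Kolmogorov-Smirnov test with the asymptotic
Kolmogorov p-value. Pettitt and Mann-Kendall are rank-based and therefore
invariant to any strictly monotone transform of the data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ChangePointResult",
    "TrendResult",
    "PeriodComparison",
    "pettitt",
    "mann_kendall",
    "theil_sen",
    "ks_two_sample",
    "compare_periods",
]


@dataclass
class ChangePointResult:
    change_year: int  # last year of the first segment
    K: float
    p: float
    mean_before: float
    mean_after: float
    u: np.ndarray  # U_t for t = 1..n-1


@dataclass
class TrendResult:
    sen_slope: float
    sen_intercept: float
    mk_S: int
    mk_varS: float
    mk_z: float
    mk_p: float
    n: int


@dataclass
class PeriodComparison:
    split_year: int
    mean_before: float
    sd_before: float
    mean_after: float
    sd_after: float
    ks_D: float
    ks_p: float
    trend_before: TrendResult
    trend_after: TrendResult
    trend_overall: TrendResult


def _as_year_series(x) -> pd.Series:
    if isinstance(x, pd.Series):
        return x.dropna().sort_index()
    v = np.asarray(x, dtype=float)
    return pd.Series(v, index=np.arange(len(v)))


def pettitt(series: pd.Series | np.ndarray) -> ChangePointResult:
    """Pettitt's rank-based single change-point test.

    U_t = sum_{i<=t} sum_{j>t} sgn(x_i - x_j); the split maximizing |U_t|
    (earliest on ties) estimates the last index of the first regime, with
    the approximate significance p = 2*exp(-6 K^2 / (n^3 + n^2)) capped
    at 1.
    """
    s = _as_year_series(series)
    x = s.to_numpy()
    n = len(x)
    if n < 10:
        raise ValueError("Pettitt test needs n >= 10")
    sign = np.sign(x[:, None] - x[None, :])
    v = sign.sum(axis=1)  # V_t = sum_j sgn(x_t - x_j)
    u = np.cumsum(v)[:-1]  # U_t for t = 1..n-1
    k_idx = int(np.argmax(np.abs(u)))  # earliest argmax on ties
    K = float(np.abs(u[k_idx]))
    p = min(1.0, 2.0 * np.exp(-6.0 * K**2 / (n**3 + n**2)))
    return ChangePointResult(
        change_year=int(s.index[k_idx]),
        K=K,
        p=p,
        mean_before=float(x[: k_idx + 1].mean()),
        mean_after=float(x[k_idx + 1 :].mean()),
        u=u,
    )


def mann_kendall(series: pd.Series | np.ndarray) -> TrendResult:
    """Mann-Kendall trend test plus the Theil-Sen slope.

    S = sum_{i<j} sgn(x_j - x_i); Var(S) carries the tie correction
    [n(n-1)(2n+5) - sum_g t_g(t_g-1)(2t_g+5)]/18; z uses the +-1
    continuity correction (0 when S = 0); p is two-sided normal.
    """
    s = _as_year_series(series)
    x = s.to_numpy()
    t = s.index.to_numpy(dtype=float)
    n = len(x)
    if n < 8:
        raise ValueError("Mann-Kendall needs n >= 8")
    diff_sign = np.sign(x[None, :] - x[:, None])
    S = int(np.triu(diff_sign, k=1).sum())
    _, counts = np.unique(x, return_counts=True)
    ties = counts[counts > 1]
    var_s = (n * (n - 1) * (2 * n + 5) - np.sum(ties * (ties - 1) * (2 * ties + 5))) / 18.0
    if var_s <= 0:  # all values tied
        z = 0.0
    elif S > 0:
        z = (S - 1) / np.sqrt(var_s)
    elif S < 0:
        z = (S + 1) / np.sqrt(var_s)
    else:
        z = 0.0
    p = 2.0 * stats.norm.sf(abs(z)) if z != 0.0 else 1.0
    slope, intercept = theil_sen(s)
    return TrendResult(
        sen_slope=slope,
        sen_intercept=intercept,
        mk_S=S,
        mk_varS=float(var_s),
        mk_z=float(z),
        mk_p=float(min(1.0, p)),
        n=n,
    )


def theil_sen(series: pd.Series | np.ndarray) -> tuple[float, float]:
    """Theil-Sen estimator: median pairwise slope and median-residual intercept."""
    s = _as_year_series(series)
    x = s.to_numpy()
    t = s.index.to_numpy(dtype=float)
    if len(x) < 3:
        raise ValueError("Theil-Sen needs n >= 3")
    if len(np.unique(t)) < 2:
        raise ValueError("need >= 2 distinct time points")
    slope, _, _, _ = stats.theilslopes(x, t)
    intercept = float(np.median(x - slope * t))
    return float(slope), intercept


def _kolmogorov_sf(lam: float, tol: float = 1e-10) -> float:
    """Asymptotic Kolmogorov survival function 2*sum (-1)^{k-1} exp(-2k^2 lam^2)."""
    if lam <= 0:
        return 1.0
    total = 0.0
    for k in range(1, 101):
        term = 2.0 * (-1.0) ** (k - 1) * np.exp(-2.0 * k**2 * lam**2)
        total += term
        if abs(term) < tol:
            break
    return float(min(1.0, max(0.0, total)))


def ks_two_sample(sample_a, sample_b) -> tuple[float, float]:
    """Two-sample KS statistic D and asymptotic p.

    D = sup_x |F_a(x) - F_b(x)| over the pooled sample points; p from the
    Kolmogorov distribution at sqrt(n_a n_b/(n_a + n_b)) * D.
    """
    a = np.sort(np.asarray(sample_a, dtype=float))
    b = np.sort(np.asarray(sample_b, dtype=float))
    if len(a) < 5 or len(b) < 5:
        raise ValueError("both samples need n >= 5")
    pooled = np.concatenate([a, b])
    fa = np.searchsorted(a, pooled, side="right") / len(a)
    fb = np.searchsorted(b, pooled, side="right") / len(b)
    d = float(np.max(np.abs(fa - fb)))
    en = len(a) * len(b) / (len(a) + len(b))
    p = _kolmogorov_sf(np.sqrt(en) * d)
    return d, p


def compare_periods(
    series: pd.Series, split_year: int, standardize: bool = True
) -> PeriodComparison:
    """Dry-vs-wet style comparison of the series before/after a split year.

    The series is z-scored over its full span first (the convention the
    period summaries are reported in), then segment means/SDs, a
    two-sample KS test between segments, and Mann-Kendall/Theil-Sen
    trends per segment and overall are computed. `split_year` is the
    last year of the first segment.
    """
    s = series.dropna().sort_index()
    if standardize:
        mu, sd = s.mean(), s.std(ddof=1)
        if sd <= 0:
            raise ValueError("zero-variance series")
        s = (s - mu) / sd
    before = s[s.index <= split_year]
    after = s[s.index > split_year]
    if len(before) < 8 or len(after) < 8:
        raise ValueError("both segments need >= 8 years")
    d, p = ks_two_sample(before.to_numpy(), after.to_numpy())
    return PeriodComparison(
        split_year=split_year,
        mean_before=float(before.mean()),
        sd_before=float(before.std(ddof=1)),
        mean_after=float(after.mean()),
        sd_after=float(after.std(ddof=1)),
        ks_D=d,
        ks_p=p,
        trend_before=mann_kendall(before),
        trend_after=mann_kendall(after),
        trend_overall=mann_kendall(s),
    )
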