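"""Chronology-climate relationships: bootstrapped correlation functions
and prewhitened seasonal correlations.

The correlation function screens which months of the climate year (from
June of the previous growing season through September of the current one)
drive a tree-ring chronology: each month/variable cell is a Pearson
correlation with a percentile bootstrap confidence interval obtained by
resampling years with replacement. The seasonal correlations are the
summer (JJA) cross table between tree-ring variables and climate, with
both sides prewhitened (AR(1) residuals, z-scored) before correlating so
first-order persistence does not inflate significance.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .rings import prewhiten

P_REPORT_FLOOR = 1e-15

__all__ = [
    "default_window",
    "correlation_function",
    "seasonal_correlation",
    "table1_analog",
    "significance_stars",
]


def default_window() -> list[tuple[str, int]]:
    """Previous-year June through current-year September."""
    return [("prev", m) for m in range(6, 13)] + [("curr", m) for m in range(1, 10)]


def _month_label(rel: str, month: int) -> str:
    import calendar

    name = calendar.month_abbr[month]
    return name.lower() if rel == "prev" else name


def correlation_function(
    chronology: pd.Series,
    monthly_climate: pd.DataFrame,
    variables: list[str],
    window: list[tuple[str, int]] | None = None,
    n_boot: int = 1000,
    alpha: float = 0.05,
    seed: int = 20140901,
) -> pd.DataFrame:
    """Bootstrapped monthly correlation function of a chronology.

    Parameters
    ----------
    chronology : year-indexed series (e.g. residual BAI chronology).
    monthly_climate : long table with year, month and the variables.
    window : (relation, month) pairs, relation "prev" or "curr";
        defaults to previous June .. current September.
    n_boot : bootstrap replicates (years resampled iid with replacement).
    alpha : two-sided CI level; a cell is significant when the
        (alpha/2, 1-alpha/2) percentile interval excludes zero.

    Returns one row per variable x month with r, ci_low, ci_high,
    significant, n.
    """
    if window is None:
        window = default_window()
    if n_boot < 200:
        raise ValueError("n_boot must be >= 200")
    rng = np.random.default_rng(seed)
    chron = chronology.dropna()
    rows = []
    # build the aligned design once per (variable, month)
    for var in variables:
        wide = monthly_climate.pivot_table(index="year", columns="month", values=var)
        for rel, month in window:
            col = wide[month]
            if rel == "prev":
                col = col.copy()
                col.index = col.index + 1  # previous-year value aligned to current year
            joined = pd.concat([chron, col], axis=1, join="inner").dropna()
            n = len(joined)
            if n < 20:
                raise ValueError(
                    f"overlap {n} < 20 years for {var} / {rel} month {month}"
                )
            x = joined.iloc[:, 0].to_numpy()
            y = joined.iloc[:, 1].to_numpy()
            if np.std(y) == 0 or np.std(x) == 0:
                rows.append(
                    {
                        "variable": var,
                        "month": _month_label(rel, month),
                        "r": np.nan,
                        "ci_low": np.nan,
                        "ci_high": np.nan,
                        "significant": False,
                        "n": n,
                        "flag": "zero variance",
                    }
                )
                continue
            r = float(np.corrcoef(x, y)[0, 1])
            idx = rng.integers(0, n, size=(n_boot, n))
            bx, by = x[idx], y[idx]
            bx = bx - bx.mean(axis=1, keepdims=True)
            by = by - by.mean(axis=1, keepdims=True)
            denom = np.sqrt((bx**2).sum(axis=1) * (by**2).sum(axis=1))
            with np.errstate(invalid="ignore", divide="ignore"):
                boot_r = (bx * by).sum(axis=1) / denom
            boot_r = boot_r[np.isfinite(boot_r)]
            lo, hi = np.percentile(boot_r, [100 * alpha / 2, 100 * (1 - alpha / 2)])
            rows.append(
                {
                    "variable": var,
                    "month": _month_label(rel, month),
                    "r": r,
                    "ci_low": float(lo),
                    "ci_high": float(hi),
                    "significant": bool(lo > 0 or hi < 0),
                    "n": n,
                    "flag": "",
                }
            )
    return pd.DataFrame(rows)


def seasonal_correlation(
    treering_series: pd.Series,
    seasonal_climate_series: pd.Series,
    prewhiten_flag: bool = True,
) -> tuple[float, float, int]:
    """Pearson correlation between two annual series, prewhitened first.

    Returns (r, two-sided p from the t transform with n-2 df, n).
    """
    joined = pd.concat(
        [treering_series, seasonal_climate_series], axis=1, join="inner"
    ).dropna()
    if len(joined) < 10:
        raise ValueError(f"aligned overlap {len(joined)} < 10 years")
    a = joined.iloc[:, 0]
    b = joined.iloc[:, 1]
    if prewhiten_flag:
        a, b = prewhiten(a), prewhiten(b)
    n = len(a)
    r = float(np.corrcoef(a, b)[0, 1])
    if abs(r) >= 1.0:
        p = P_REPORT_FLOOR
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
        p = max(2.0 * stats.t.sf(abs(t), n - 2), P_REPORT_FLOOR)
    return r, float(p), n


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def table1_analog(
    chronologies: dict[str, pd.Series],
    seasonal_climate: dict[str, pd.Series],
    prewhiten_flag: bool = True,
) -> pd.DataFrame:
    """Full cross table of prewhitened seasonal correlations with stars.

    Rows are tree-ring variables (BAI, Delta13C, iWUE, d18O analogs),
    columns climate variables (e.g. tmax, prcp, vpdmax, wbal); each cell
    carries r, p, n and significance stars at 0.05/0.01/0.001.
    """
    rows = []
    for tr_name, tr in chronologies.items():
        for cl_name, cl in seasonal_climate.items():
            r, p, n = seasonal_correlation(tr, cl, prewhiten_flag)
            rows.append(
                {
                    "treering": tr_name,
                    "climate": cl_name,
                    "r": r,
                    "p": p,
                    "n": n,
                    "stars": significance_stars(p),
                }
            )
    return pd.DataFrame(rows)
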