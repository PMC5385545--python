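"""Ring-width series, basal area increment, and Regional Curve Standardization.

Growth change over a century is analyzed in basal-area-increment (BAI)
space, where a ring of width w added at radius r contributes an annulus
area pi*((r+w)^2 - r^2). Age-related trends are removed by RCS: raw BAI
series are aligned on cambial age, averaged into a regional curve, and
each tree is divided by that curve, giving dimensionless residual BAI
that retains low-frequency, externally forced variance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

__all__ = [
    "TreeRingSeries",
    "BAISeries",
    "RegionalCurve",
    "to_bai",
    "build_regional_curve",
    "rcs_detrend",
    "build_chronology",
    "eps",
    "prewhiten",
]

log = logging.getLogger(__name__)


@dataclass
class TreeRingSeries:
    """Per-tree annual ring widths in mm, innermost ring first."""

    tree_id: str
    first_year: int
    widths: np.ndarray
    pith_offset: float = 0.0  # estimated missing radius to pith, mm

    def __post_init__(self):
        self.widths = np.asarray(self.widths, dtype=float)
        if self.widths.ndim != 1 or len(self.widths) < 1:
            raise ValueError(f"{self.tree_id}: need a 1-d series of length >= 1")
        if not np.all(np.isfinite(self.widths)) or np.any(self.widths <= 0):
            raise ValueError(f"{self.tree_id}: widths must be positive and finite")
        if self.pith_offset < 0:
            raise ValueError(f"{self.tree_id}: negative pith offset")

    @property
    def years(self) -> np.ndarray:
        return self.first_year + np.arange(len(self.widths))

    def to_series(self) -> pd.Series:
        return pd.Series(self.widths, index=self.years, name=self.tree_id)


@dataclass
class BAISeries:
    """Per-tree annual basal area increments in mm^2 with 1-based cambial age."""

    tree_id: str
    first_year: int
    bai: np.ndarray
    cambial_age: np.ndarray

    def __post_init__(self):
        self.bai = np.asarray(self.bai, dtype=float)
        self.cambial_age = np.asarray(self.cambial_age, dtype=int)
        if np.any(self.bai <= 0):
            raise ValueError(f"{self.tree_id}: BAI must be positive")
        if np.any(np.diff(self.cambial_age) != 1):
            raise ValueError(f"{self.tree_id}: cambial age must increase by 1")

    @property
    def years(self) -> np.ndarray:
        return self.first_year + np.arange(len(self.bai))

    def to_series(self) -> pd.Series:
        return pd.Series(self.bai, index=self.years, name=self.tree_id)


@dataclass
class RegionalCurve:
    """Mean BAI at each cambial age across trees (the regional curve)."""

    age: np.ndarray
    mean_bai: np.ndarray
    n_trees: np.ndarray

    def lookup(self, ages: np.ndarray) -> np.ndarray:
        """Curve value at each requested age; NaN where not covered."""
        mapping = pd.Series(self.mean_bai, index=self.age)
        return mapping.reindex(ages).to_numpy()


def to_bai(series: TreeRingSeries, pith_age_offset: int = 0) -> BAISeries:
    """Convert ring widths to basal area increments.

    Radii accumulate from the pith offset; the increment at year t is the
    annulus pi*(r_t^2 - r_{t-1}^2). The sum of a tree's BAI therefore
    telescopes to pi*(total radius)^2 - pi*pith_offset^2 exactly.
    """
    r = series.pith_offset + np.cumsum(series.widths)
    r_prev = np.concatenate([[series.pith_offset], r[:-1]])
    bai = np.pi * (r**2 - r_prev**2)
    age = 1 + pith_age_offset + np.arange(len(bai))
    return BAISeries(series.tree_id, series.first_year, bai, age)


def build_regional_curve(
    bai_collection: list[BAISeries],
    min_trees: int = 3,
    smooth_window: int | None = None,
) -> RegionalCurve:
    """Mean BAI by cambial age, truncated to well-replicated ages, smoothed.

    The curve is cut where fewer than `min_trees` trees contribute and then
    smoothed with a centered moving average of width `smooth_window`
    (default max(5, 10% of the oldest retained age); 1 disables smoothing).
    """
    if not bai_collection:
        raise ValueError("empty BAI collection")
    if len(bai_collection) < 2:
        raise ValueError("regional curve needs >= 2 trees")
    by_age = pd.DataFrame(
        {s.tree_id: pd.Series(s.bai, index=s.cambial_age) for s in bai_collection}
    )
    n = by_age.notna().sum(axis=1)
    keep = by_age.index[n >= min_trees]
    if len(keep) == 0:
        raise ValueError(f"no cambial age reaches min_trees={min_trees}")
    last_age = keep.max()
    by_age = by_age.loc[by_age.index <= last_age]
    mean = by_age.mean(axis=1)
    if smooth_window is None:
        smooth_window = max(5, int(round(0.10 * last_age)))
    if smooth_window > 1:
        mean = mean.rolling(smooth_window, center=True, min_periods=1).mean()
    if np.any(mean.to_numpy() <= 0):
        raise ValueError("regional curve non-positive after smoothing")
    return RegionalCurve(
        age=mean.index.to_numpy(),
        mean_bai=mean.to_numpy(),
        n_trees=n.loc[mean.index].to_numpy(),
    )


def rcs_detrend(
    bai_collection: list[BAISeries], curve: RegionalCurve
) -> dict[str, pd.Series]:
    """Divide each tree's BAI by the regional curve at its cambial age.

    Returns year-indexed dimensionless residual series per tree. Rings at
    ages beyond the curve's coverage are dropped with a logged warning.
    """
    out: dict[str, pd.Series] = {}
    for s in bai_collection:
        rc = curve.lookup(s.cambial_age)
        covered = np.isfinite(rc)
        if not covered.all():
            log.warning(
                "tree %s: dropping %d rings beyond regional-curve coverage",
                s.tree_id,
                int((~covered).sum()),
            )
        if np.any(rc[covered] <= 0):
            raise ValueError(f"regional curve <= 0 at ages needed by {s.tree_id}")
        resid = pd.Series(
            s.bai[covered] / rc[covered], index=s.years[covered], name=s.tree_id
        )
        out[s.tree_id] = resid
    return out


def build_chronology(residuals: dict[str, pd.Series]) -> pd.DataFrame:
    """Arithmetic mean across trees per calendar year, with sample depth."""
    if not residuals:
        raise ValueError("no series to aggregate")
    wide = pd.DataFrame(residuals)
    chron = pd.DataFrame(
        {
            "value": wide.mean(axis=1),
            "sample_depth": wide.notna().sum(axis=1),
        }
    )
    chron = chron[chron["sample_depth"] >= 1]
    chron.index.name = "year"
    return chron.sort_index()


def eps(
    series_collection: list[TreeRingSeries] | dict[str, pd.Series],
    common_period: tuple[int, int] | None = None,
) -> tuple[float, float, int]:
    """Expressed population signal of a chronology.

    EPS = n*rbar / (n*rbar + (1 - rbar)) with rbar the mean pairwise
    Pearson correlation over the common period and n the number of trees.
    The conventional adequacy threshold is 0.85.
    """
    if isinstance(series_collection, dict):
        wide = pd.DataFrame(series_collection)
    else:
        wide = pd.DataFrame({s.tree_id: s.to_series() for s in series_collection})
    if wide.shape[1] < 2:
        raise ValueError("EPS needs >= 2 series")
    if common_period is not None:
        lo, hi = common_period
        wide = wide.loc[(wide.index >= lo) & (wide.index <= hi)]
    wide = wide.dropna()
    if len(wide) < 10:
        raise ValueError("common overlap shorter than 10 years")
    cols = list(wide.columns)
    rs = [wide[a].corr(wide[b]) for a, b in combinations(cols, 2)]
    rbar = float(np.mean(rs))
    n = len(cols)
    value = n * rbar / (n * rbar + (1.0 - rbar))
    return value, rbar, n


def prewhiten(x: np.ndarray | pd.Series) -> np.ndarray | pd.Series:
    """Remove first-order autocorrelation and z-score the residuals.

    The lag-1 coefficient is the Yule-Walker estimate
    phi = sum((x_t - xbar)(x_{t-1} - xbar)) / sum((x_t - xbar)^2);
    residuals x_t - phi*x_{t-1} for t >= 2 are standardized to mean 0,
    SD 1 (ddof=1). Output is one observation shorter than the input.
    """
    is_series = isinstance(x, pd.Series)
    idx = x.index[1:] if is_series else None
    v = np.asarray(x, dtype=float)
    if len(v) < 10:
        raise ValueError("prewhitening needs length >= 10")
    c = v - v.mean()
    denom = np.sum(c**2)
    if denom <= 0:
        raise ValueError("zero-variance input")
    phi = np.sum(c[1:] * c[:-1]) / denom
    resid = v[1:] - phi * v[:-1]
    sd = resid.std(ddof=1)
    if sd <= 0:
        raise ValueError("zero variance after prewhitening")
    z = (resid - resid.mean()) / sd
    return pd.Series(z, index=idx, name=getattr(x, "name", None)) if is_series else z
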