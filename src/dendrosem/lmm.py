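"""Random-intercept linear mixed models fit by REML.

The model is y = X beta + u_g + e with one random intercept per group
(tree), u_g ~ N(0, sigma_u^2), e ~ N(0, sigma_e^2). Estimation profiles
the variance ratio lambda = sigma_u^2 / sigma_e^2: for fixed lambda the
marginal covariance is sigma_e^2 (I + lambda Z Z'), whose blockwise
inverse is available in closed form (Sherman-Morrison per group), so the
restricted likelihood reduces to a smooth one-dimensional function of
lambda that is minimized numerically with the boundary lambda = 0
admitted. Fixed-effect inference uses t statistics with the containment
style degrees of freedom n - rank(X) - (n_groups - 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = ["LMMFit", "fit_lmm", "standardize_paths", "r2_mixed"]


@dataclass
class LMMFit:
    response: str
    predictors: list[str]
    params: pd.Series  # fixed-effect estimates, index = ['Intercept', ...]
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    sigma_u2: float
    sigma_e2: float
    n_obs: int
    n_groups: int
    df_resid: int
    reml_criterion: float  # -2 * restricted log-likelihood at the optimum
    fitted: np.ndarray  # X beta-hat (population level)
    group_effects: pd.Series  # BLUPs of the random intercepts
    frame: pd.DataFrame = field(repr=False)  # analysis rows actually used

    @property
    def lambda_ratio(self) -> float:
        return self.sigma_u2 / self.sigma_e2 if self.sigma_e2 > 0 else np.inf


def _profile_pieces(lmbda, xtx, xty, yty, gx, gy, m, n, p):
    """GLS quantities for V = I + lambda Z Z' via per-group rank-one downdates."""
    c = lmbda / (1.0 + lmbda * m)  # per group
    a = xtx - (gx.T * c) @ gx  # X' V^-1 X
    b = xty - gx.T @ (c * gy)  # X' V^-1 y
    q = yty - np.sum(c * gy**2)  # y' V^-1 y
    beta = np.linalg.solve(a, b)
    rss = q - 2.0 * beta @ b + beta @ a @ beta
    rss = max(rss, 1e-300)
    sigma_e2 = rss / (n - p)
    logdet_v = np.sum(np.log1p(lmbda * m))
    sign, logdet_a = np.linalg.slogdet(a)
    crit = (
        (n - p) * np.log(sigma_e2)
        + logdet_v
        + logdet_a
        + (n - p) * (1.0 + np.log(2.0 * np.pi))
    )
    return crit, beta, sigma_e2, a


def reml_criterion(lmbda: float, y, x, codes, n_groups) -> float:
    """-2 restricted log-likelihood at variance ratio `lmbda` (for diagnostics)."""
    n, p = x.shape
    m = np.bincount(codes, minlength=n_groups).astype(float)
    gx = np.vstack([x[codes == g].sum(axis=0) for g in range(n_groups)])
    gy = np.array([y[codes == g].sum() for g in range(n_groups)])
    crit, *_ = _profile_pieces(lmbda, x.T @ x, x.T @ y, y @ y, gx, gy, m, n, p)
    return crit


def fit_lmm(
    data: pd.DataFrame,
    response: str,
    predictors: list[str],
    group: str,
    add_intercept: bool = True,
) -> LMMFit:
    """Fit the random-intercept model `response ~ predictors + (1 | group)` by REML.

    Raises on rank-deficient fixed-effect designs (naming the collinear
    columns) and on single-group data, for which ordinary regression is
    the right tool.
    """
    cols = [response, *predictors, group]
    frame = data[cols].dropna().reset_index(drop=True)
    y = frame[response].to_numpy(dtype=float)
    x = frame[predictors].to_numpy(dtype=float)
    if add_intercept:
        x = np.column_stack([np.ones(len(frame)), x])
        names = ["Intercept", *predictors]
    else:
        names = list(predictors)
    n, p = x.shape
    if n < 10:
        raise ValueError(f"need >= 10 observations, got {n}")
    groups, codes = np.unique(frame[group], return_inverse=True)
    n_groups = len(groups)
    if n_groups < 2:
        raise ValueError("single group: use ordinary regression instead")
    rank = np.linalg.matrix_rank(x)
    if rank < p:
        # identify columns whose removal restores full rank
        bad = [
            names[j]
            for j in range(p)
            if np.linalg.matrix_rank(np.delete(x, j, axis=1)) == rank
        ]
        raise ValueError(f"rank-deficient fixed-effect design; collinear columns: {bad}")

    m = np.bincount(codes, minlength=n_groups).astype(float)
    gx = np.vstack([x[codes == g].sum(axis=0) for g in range(n_groups)])
    gy = np.array([y[codes == g].sum() for g in range(n_groups)])
    xtx, xty, yty = x.T @ x, x.T @ y, y @ y

    def crit(log_lmbda: float) -> float:
        return _profile_pieces(np.exp(log_lmbda), xtx, xty, yty, gx, gy, m, n, p)[0]

    # grid over log-lambda plus the lambda = 0 boundary, then local refinement
    grid = np.linspace(-12.0, 8.0, 41)
    vals = [crit(g) for g in grid]
    c0 = _profile_pieces(0.0, xtx, xty, yty, gx, gy, m, n, p)[0]
    j = int(np.argmin(vals))
    lo = grid[max(j - 1, 0)]
    hi = grid[min(j + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        crit, bounds=(lo, hi), method="bounded", options={"xatol": 1e-12}
    )
    if c0 <= res.fun:
        lmbda, best = 0.0, c0
    else:
        lmbda, best = float(np.exp(res.x)), float(res.fun)

    _, beta, sigma_e2, a = _profile_pieces(lmbda, xtx, xty, yty, gx, gy, m, n, p)
    sigma_u2 = lmbda * sigma_e2
    cov_beta = np.linalg.inv(a) * sigma_e2
    se = np.sqrt(np.diag(cov_beta))
    tvals = beta / se
    df = n - rank - (n_groups - 1)
    if df < 1:
        raise ValueError("non-positive residual degrees of freedom")
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df)
    fitted = x @ beta
    # BLUPs: shrunken group means of marginal residuals
    resid = y - fitted
    shrink = lmbda * m / (1.0 + lmbda * m)
    group_sums = np.array([resid[codes == g].sum() for g in range(n_groups)])
    blups = shrink * group_sums / np.maximum(m, 1)

    return LMMFit(
        response=response,
        predictors=list(predictors),
        params=pd.Series(beta, index=names),
        bse=pd.Series(se, index=names),
        tvalues=pd.Series(tvals, index=names),
        pvalues=pd.Series(np.minimum(pvals, 1.0), index=names),
        sigma_u2=float(sigma_u2),
        sigma_e2=float(sigma_e2),
        n_obs=n,
        n_groups=n_groups,
        df_resid=int(df),
        reml_criterion=float(best),
        fitted=fitted,
        group_effects=pd.Series(blups, index=groups),
        frame=frame,
    )


def standardize_paths(fit: LMMFit) -> pd.Series:
    """Standardized coefficients beta * SD(x) / SD(y) over the analysis rows."""
    sdy = fit.frame[fit.response].std(ddof=1)
    if sdy <= 0:
        raise ValueError("zero SD response")
    out = {}
    for name in fit.predictors:
        sdx = fit.frame[name].std(ddof=1)
        if sdx <= 0:
            raise ValueError(f"zero SD predictor {name}")
        out[name] = fit.params[name] * sdx / sdy
    return pd.Series(out)


def r2_mixed(fit: LMMFit) -> tuple[float, float]:
    """Marginal and conditional R^2 for a random-intercept model.

    Marginal = var(X beta) / (var(X beta) + sigma_u^2 + sigma_e^2);
    conditional adds sigma_u^2 to the numerator.
    """
    var_f = float(np.var(fit.fitted, ddof=1)) if len(fit.fitted) > 1 else 0.0
    denom = var_f + fit.sigma_u2 + fit.sigma_e2
    return var_f / denom, (var_f + fit.sigma_u2) / denom
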