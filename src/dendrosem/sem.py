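"""Piecewise structural equation modeling with tree-level random intercepts.

A path diagram over observed variables is estimated locally: each
endogenous node gets its own linear mixed model (random intercept on
tree identity), giving raw and standardized path coefficients and
marginal/conditional R^2. Global fit is judged by d-separation: every
conditional-independence claim implied by the missing edges is tested by
regression, and the claim p-values are combined with Fisher's
C = -2 sum ln p ~ chi-square(2k). Model comparison uses AICc with K the
total number of parameters across component models.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .lmm import LMMFit, fit_lmm, r2_mixed, standardize_paths

__all__ = [
    "SEMSpec",
    "IndependenceClaim",
    "SEMFit",
    "basis_set",
    "dsep_pvalues",
    "fishers_c",
    "aicc_sem",
    "fit_sem",
]

P_FLOOR = 1e-12


@dataclass(frozen=True)
class IndependenceClaim:
    """dependent _||_ independent | conditioning_set"""

    dependent: str
    independent: str
    conditioning: tuple[str, ...]

    def __str__(self):
        cond = ", ".join(self.conditioning) if self.conditioning else "{}"
        return f"{self.dependent} _||_ {self.independent} | {{{cond}}}"


@dataclass
class SEMSpec:
    """A directed acyclic path diagram over observed, standardizable variables.

    Exogenous nodes (drivers) have no parents and their mutual covariances
    are free; endogenous nodes each get a component mixed model. Unordered
    `correlated_errors` pairs are the double-headed arrows: their residual
    covariance is free, so they are excluded from the d-separation basis
    set and summarized as residual correlations instead.
    """

    exogenous: list[str]
    endogenous: list[str]
    edges: list[tuple[str, str]]
    correlated_errors: list[tuple[str, str]] = field(default_factory=list)
    group: str = "tree_id"

    def __post_init__(self):
        nodes = set(self.exogenous) | set(self.endogenous)
        if set(self.exogenous) & set(self.endogenous):
            raise ValueError("a node cannot be both exogenous and endogenous")
        for src, dst in self.edges:
            if src not in nodes or dst not in nodes:
                raise ValueError(f"edge ({src}, {dst}) references unknown node")
            if dst in self.exogenous:
                raise ValueError(f"edge into exogenous node {dst}")
        g = nx.DiGraph(self.edges)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("directed part of the path diagram is cyclic")
        directed = {frozenset(e) for e in self.edges}
        for pair in self.correlated_errors:
            fs = frozenset(pair)
            if len(fs) != 2 or not fs <= nodes:
                raise ValueError(f"bad correlated-error pair {pair}")
            if fs in directed:
                raise ValueError(f"correlated-error pair {pair} duplicates a directed edge")
        for node in self.endogenous:
            if not self.parents(node):
                raise ValueError(f"endogenous node {node} has no parents")

    @property
    def nodes(self) -> list[str]:
        return list(self.exogenous) + list(self.endogenous)

    def parents(self, node: str) -> list[str]:
        return sorted(src for src, dst in self.edges if dst == node)

    def topological_order(self) -> list[str]:
        """Exogenous first (name order), then endogenous in topological order
        with name-order tie-breaks."""
        g = nx.DiGraph()
        g.add_nodes_from(self.endogenous)
        g.add_edges_from((s, d) for s, d in self.edges if s in self.endogenous)
        endo = list(nx.lexicographical_topological_sort(g))
        return sorted(self.exogenous) + endo


def basis_set(spec: SEMSpec) -> list[IndependenceClaim]:
    """The d-separation basis set implied by the diagram's missing edges.

    One claim per unordered non-adjacent pair, skipping pairs that are
    both exogenous (free covariance) and declared correlated-error pairs.
    The topologically later node is the regression target; the
    conditioning set is the union of both nodes' direct parents.
    """
    order = spec.topological_order()
    rank = {v: i for i, v in enumerate(order)}
    adjacent = {frozenset(e) for e in spec.edges}
    excluded = {frozenset(p) for p in spec.correlated_errors}
    claims = []
    for a, b in itertools.combinations(order, 2):
        fs = frozenset((a, b))
        if fs in adjacent or fs in excluded:
            continue
        if a in spec.exogenous and b in spec.exogenous:
            continue
        dep, indep = (a, b) if rank[a] > rank[b] else (b, a)
        cond = sorted((set(spec.parents(a)) | set(spec.parents(b))) - {a, b})
        claims.append(IndependenceClaim(dep, indep, tuple(cond)))
    return claims


def _claim_pvalue(claim: IndependenceClaim, spec: SEMSpec, data: pd.DataFrame) -> float:
    predictors = [claim.independent, *claim.conditioning]
    if claim.dependent in spec.endogenous:
        fit = fit_lmm(data, claim.dependent, predictors, spec.group)
        p = fit.pvalues[claim.independent]
    else:  # plain regression for an exogenous target
        frame = data[[claim.dependent, *predictors]].dropna()
        x = np.column_stack([np.ones(len(frame)), frame[predictors].to_numpy()])
        y = frame[claim.dependent].to_numpy()
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        resid = y - x @ beta
        df = len(frame) - x.shape[1]
        s2 = resid @ resid / df
        cov = s2 * np.linalg.inv(x.T @ x)
        t = beta[1] / np.sqrt(cov[1, 1])
        p = 2.0 * stats.t.sf(abs(t), df)
    return float(max(p, P_FLOOR))


def dsep_pvalues(spec: SEMSpec, data: pd.DataFrame) -> pd.DataFrame:
    """Test every basis-set claim; returns claims with their p-values."""
    claims = basis_set(spec)
    rows = [
        {"claim": str(c), "dependent": c.dependent, "independent": c.independent,
         "conditioning": ", ".join(c.conditioning), "p": _claim_pvalue(c, spec, data)}
        for c in claims
    ]
    return pd.DataFrame(rows, columns=["claim", "dependent", "independent", "conditioning", "p"])


def fishers_c(p_values) -> tuple[float, int, float]:
    """Fisher's C = -2 sum ln p, df = 2k, and its chi-square upper-tail p.

    An empty claim set is the saturated-model convention: C = 0, df = 0,
    global p = 1.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return 0.0, 0, 1.0
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    c = float(-2.0 * np.sum(np.log(p)))
    df = 2 * p.size
    return c, df, float(stats.chi2.sf(c, df))


def aicc_sem(c: float, k: int, n: int) -> float:
    """Small-sample AICc of a piecewise SEM: C + 2K n/(n - K - 1)."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= K+1={k + 1}")
    return float(c + 2.0 * k * n / (n - k - 1))


@dataclass
class SEMFit:
    spec: SEMSpec
    component_fits: dict[str, LMMFit]
    paths: pd.DataFrame  # source, target, coef, std_coef, se, t, p
    claims: pd.DataFrame
    fishers_c: float
    df: int
    global_p: float
    aicc: float
    k_params: int
    n_obs: int
    r2: dict[str, tuple[float, float]]  # response -> (marginal, conditional)
    residual_correlations: pd.DataFrame
    exogenous_correlations: pd.DataFrame

    def summary(self) -> dict:
        return {
            "fishers_c": self.fishers_c,
            "df": self.df,
            "global_p": self.global_p,
            "aicc": self.aicc,
            "k_params": self.k_params,
            "n_obs": self.n_obs,
            "r2_marginal": {k: v[0] for k, v in self.r2.items()},
            "r2_conditional": {k: v[1] for k, v in self.r2.items()},
        }


def fit_sem(spec: SEMSpec, data: pd.DataFrame) -> SEMFit:
    """Fit every component mixed model and assemble the global SEM summary.

    `data` must hold one row per tree x year with all node columns plus
    the grouping column (exogenous drivers replicated across trees).
    """
    needed = [*spec.nodes, spec.group]
    if "year" in data.columns and "year" not in needed:
        needed.append("year")
    missing = [c for c in needed if c not in data.columns]
    if missing:
        raise ValueError(f"data lacks columns: {missing}")
    frame = data[needed].dropna().reset_index(drop=True)
    n_obs = len(frame)

    component_fits: dict[str, LMMFit] = {}
    path_rows = []
    r2: dict[str, tuple[float, float]] = {}
    k_params = 0
    for node in spec.endogenous:
        parents = spec.parents(node)
        try:
            fit = fit_lmm(frame, node, parents, spec.group)
            std = standardize_paths(fit)
        except Exception as exc:
            raise RuntimeError(f"component model for '{node}' failed: {exc}") from exc
        component_fits[node] = fit
        for parent in parents:
            path_rows.append(
                {
                    "source": parent,
                    "target": node,
                    "coef": fit.params[parent],
                    "std_coef": std[parent],
                    "se": fit.bse[parent],
                    "t": fit.tvalues[parent],
                    "p": fit.pvalues[parent],
                }
            )
        r2[node] = r2_mixed(fit)
        k_params += len(fit.params) + 2  # fixed effects + two variance components

    claims = dsep_pvalues(spec, frame)
    c, df, global_p = fishers_c(claims["p"]) if len(claims) else (0.0, 0, 1.0)
    aicc = aicc_sem(c, k_params, n_obs)

    # residual correlations for the double-headed arrows
    resid_rows = []
    for a, b in spec.correlated_errors:
        if a in component_fits and b in component_fits:
            ra = _conditional_residuals(component_fits[a], spec.group)
            rb = _conditional_residuals(component_fits[b], spec.group)
            joined = pd.concat([ra, rb], axis=1, join="inner")
            r = float(joined.iloc[:, 0].corr(joined.iloc[:, 1]))
            resid_rows.append({"a": a, "b": b, "residual_r": r})
    resid_cor = pd.DataFrame(resid_rows, columns=["a", "b", "residual_r"])

    exog = (
        frame.groupby("year")[spec.exogenous].first()
        if "year" in frame.columns
        else frame[spec.exogenous]
    )
    exog_cor = exog.corr()

    return SEMFit(
        spec=spec,
        component_fits=component_fits,
        paths=pd.DataFrame(path_rows),
        claims=claims,
        fishers_c=c,
        df=df,
        global_p=global_p,
        aicc=aicc,
        k_params=k_params,
        n_obs=n_obs,
        r2=r2,
        residual_correlations=resid_cor,
        exogenous_correlations=exog_cor,
    )


def _conditional_residuals(fit: LMMFit, group: str) -> pd.Series:
    """Residuals after removing fixed effects and BLUP random intercepts."""
    blup = fit.group_effects.reindex(fit.frame[group]).to_numpy()
    resid = fit.frame[fit.response].to_numpy() - fit.fitted - blup
    return pd.Series(resid, index=fit.frame.index, name=fit.response)
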