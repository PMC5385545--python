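"""Carbon-isotope physiology: discrimination, ci/ca, and intrinsic water-use efficiency.

Tree-ring cellulose delta13C, together with the atmospheric delta13C and CO2
history, yields the leaf-level discrimination

    Delta13C = (d13C_atm - d13C_ring) / (1 + d13C_ring/1000)   [permil]

which under the simple (Farquhar) linear model maps to the ratio of
intercellular to ambient CO2,

    ci/ca = (Delta13C - a) / (b - a),

with a = 4.4 permil (diffusion through stomata) and b = 27 permil
(RuBisCO carboxylation). Intrinsic water-use efficiency, the ratio of
assimilation to stomatal conductance, follows as

    iWUE = ca * (1 - ci/ca) / 1.6 = ca * (b - Delta13C)/(b - a) * 0.625

in umol CO2 per mol H2O. No photorespiration or mesophyll-conductance
corrections are applied. delta18O is carried through untransformed as a
stomatal-conductance / source-water proxy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FractionationConstants",
    "discrimination",
    "cica_ratio",
    "iwue",
    "derive_physiology",
]


@dataclass(frozen=True)
class FractionationConstants:
    a: float = 4.4  # diffusion fractionation, permil
    b: float = 27.0  # carboxylation fractionation, permil
    k: float = 0.625  # 1/1.6: converts ca*(1 - ci/ca) to A/gs

    def __post_init__(self):
        if not (self.b > self.a > 0):
            raise ValueError("need b > a > 0")
        if self.k <= 0:
            raise ValueError("need k > 0")


def discrimination(d13c_ring, d13c_atm):
    """Carbon isotope discrimination Delta13C in permil."""
    d13c_ring = np.asarray(d13c_ring, dtype=float)
    if np.any(d13c_ring <= -1000.0):
        raise ValueError("d13c_ring <= -1000 permil is unphysical")
    out = (np.asarray(d13c_atm, dtype=float) - d13c_ring) / (1.0 + d13c_ring / 1000.0)
    return float(out) if np.ndim(out) == 0 else out


def ring_d13c_from_discrimination(delta13c, d13c_atm):
    """Exact inverse of :func:`discrimination`; used by the study generator."""
    delta13c = np.asarray(delta13c, dtype=float)
    out = (np.asarray(d13c_atm, dtype=float) - delta13c) / (1.0 + delta13c / 1000.0)
    return float(out) if np.ndim(out) == 0 else out


def cica_ratio(delta13c, constants: FractionationConstants = FractionationConstants()):
    """ci/ca from discrimination. Values outside (0, 1) are returned, not clamped."""
    out = (np.asarray(delta13c, dtype=float) - constants.a) / (constants.b - constants.a)
    return float(out) if np.ndim(out) == 0 else out


def iwue(delta13c, ca, constants: FractionationConstants = FractionationConstants()):
    """Intrinsic water-use efficiency in umol mol-1 at ambient CO2 `ca` (ppm)."""
    ca = np.asarray(ca, dtype=float)
    if np.any(ca <= 0):
        raise ValueError("ca must be positive (ppm)")
    cica = cica_ratio(delta13c, constants)
    out = ca * (1.0 - cica) * constants.k
    return float(out) if np.ndim(out) == 0 else out


def derive_physiology(
    isotope_table: pd.DataFrame,
    environment_table: pd.DataFrame,
    constants: FractionationConstants = FractionationConstants(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-tree physiology series plus per-year chronologies.

    Parameters
    ----------
    isotope_table : DataFrame with columns tree_id, year, d13c, d18o.
    environment_table : DataFrame with columns year, co2_ppm, d13c_atm.

    Returns
    -------
    (per_tree, chronology)
        per_tree mirrors the input with delta13c, cica, iwue and the
        atmospheric context appended, plus a `cica_in_range` flag for rows
        whose ci/ca falls outside (0, 1). chronology holds the mean over
        trees per year of delta13c, cica, iwue, d18o with sample depth.
    """
    need = {"tree_id", "year", "d13c", "d18o"}
    if not need.issubset(isotope_table.columns):
        raise ValueError(f"isotope table must have columns {sorted(need)}")
    env = environment_table.set_index("year")
    missing = sorted(set(isotope_table["year"]) - set(env.index))
    if missing:
        raise ValueError(f"no CO2/d13c_atm context for years: {missing}")
    out = isotope_table.copy()
    out["ca"] = env["co2_ppm"].reindex(out["year"]).to_numpy()
    out["d13c_atm"] = env["d13c_atm"].reindex(out["year"]).to_numpy()
    out["delta13c"] = discrimination(out["d13c"].to_numpy(), out["d13c_atm"].to_numpy())
    out["cica"] = cica_ratio(out["delta13c"].to_numpy(), constants)
    out["iwue"] = out["ca"] * (1.0 - out["cica"]) * constants.k
    out["cica_in_range"] = (out["cica"] > 0) & (out["cica"] < 1)
    chron = (
        out.groupby("year")[["delta13c", "cica", "iwue", "d18o"]]
        .mean()
        .assign(sample_depth=out.groupby("year")["tree_id"].nunique())
    )
    return out, chron
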