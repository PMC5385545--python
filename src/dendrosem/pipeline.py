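"""End-to-end orchestration: simulate or ingest, detrend, derive physiology,
compute the water balance, correlate, fit the SEMs, and test the regime shift.

Every stage reads and writes the documented plain-text contracts (RWL and
CSV), so stages are independently runnable; `run_pipeline` chains them and
writes a manifest (config hash, seeds, row counts, warnings) next to the
outputs. All randomness flows from named sub-streams of one master seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import climate as climate_mod
from . import regime, response, rings, rwl, sem, synthetic
from .isotopes import FractionationConstants, derive_physiology

__all__ = ["PipelineConfig", "validate_config", "run_pipeline"]

log = logging.getLogger(__name__)

_DEFAULTS = {
    "simulate": {},  # SyntheticConfig overrides; None => read inputs instead
    "inputs": None,  # {"rwl":..., "isotopes":..., "climate":..., "environment":...}
    "latitude": 41.4,
    "season_months": [6, 7, 8],
    "correlation_period": [1950, 2014],
    "sem_period": [1981, 2014],
    "regime_span": [1950, 2014],
    "sem_gas_exchange": ["delta13c", "iwue"],
    "n_boot": 1000,
    "alpha": 0.05,
    "min_trees": 3,
    "smooth_window": None,
    "seed": 0,
}


@dataclass
class PipelineConfig:
    simulate: dict | None = field(default_factory=dict)
    inputs: dict | None = None
    latitude: float = 41.4
    season_months: list[int] = field(default_factory=lambda: [6, 7, 8])
    correlation_period: list[int] = field(default_factory=lambda: [1950, 2014])
    sem_period: list[int] = field(default_factory=lambda: [1981, 2014])
    regime_span: list[int] = field(default_factory=lambda: [1950, 2014])
    sem_gas_exchange: list[str] = field(default_factory=lambda: ["delta13c", "iwue"])
    n_boot: int = 1000
    alpha: float = 0.05
    min_trees: int = 3
    smooth_window: int | None = None
    seed: int = 0

    def __post_init__(self):
        problems = []
        if self.simulate is None and self.inputs is None:
            problems.append("one of 'simulate' or 'inputs' must be given")
        if any(m < 1 or m > 12 for m in self.season_months) or not self.season_months:
            problems.append(f"invalid season_months: {self.season_months}")
        for name in ("correlation_period", "sem_period", "regime_span"):
            lo, hi = getattr(self, name)
            if lo >= hi:
                problems.append(f"{name} must be an increasing interval")
        if not isinstance(self.seed, int):
            problems.append("seed must be an integer")
        if self.inputs is not None:
            need = {"rwl", "isotopes", "climate", "environment"}
            missing = need - set(self.inputs)
            if missing:
                problems.append(f"inputs missing paths: {sorted(missing)}")
        if problems:
            raise ValueError("invalid pipeline config:\n- " + "\n- ".join(problems))


def validate_config(path: str | Path) -> PipelineConfig:
    """Load, default-fill, and cross-check a YAML pipeline config.

    Relative input paths are resolved against the config file's directory.
    Unknown keys are an error (itemized).
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) or {}
    unknown = set(raw) - set(_DEFAULTS)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    merged = {**_DEFAULTS, **raw}
    if merged.get("inputs"):
        merged["inputs"] = {
            k: str((path.parent / v).resolve()) for k, v in merged["inputs"].items()
        }
        if "simulate" not in raw:
            merged["simulate"] = None
    cfg = PipelineConfig(**merged)
    if cfg.simulate is not None:
        synthetic.SyntheticConfig(**{**cfg.simulate, "seed": cfg.seed})  # validate early
    return cfg


def _config_hash(cfg: PipelineConfig) -> str:
    payload = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _load_inputs(cfg: PipelineConfig):
    trees = rwl.read_rwl(cfg.inputs["rwl"])
    climate = pd.read_csv(cfg.inputs["climate"])
    if "wbal" not in climate.columns:
        climate = climate_mod.water_balance(climate, cfg.latitude)
    environment = pd.read_csv(cfg.inputs["environment"])
    isotopes = pd.read_csv(cfg.inputs["isotopes"])
    return trees, climate, environment, isotopes, None


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path | None = None) -> dict:
    """Run every stage; returns a results dict and optionally writes CSV/JSON.

    Results keys: study (when simulated), eps, chronology, physiology,
    seasonal, correlation_function, table1, sem (per gas-exchange
    variant), regime, manifest.
    """
    t0 = time.time()
    warnings_count = 0

    # --- data ---------------------------------------------------------
    if cfg.simulate is not None:
        study = synthetic.generate_study(
            synthetic.SyntheticConfig(**{**cfg.simulate, "seed": cfg.seed})
        )
        trees, climate, environment, isotopes = (
            study.trees, study.climate, study.environment, study.isotopes,
        )
    else:
        trees, climate, environment, isotopes, study = _load_inputs(cfg)

    span = (int(climate["year"].min()), int(climate["year"].max()))
    for name in ("correlation_period", "sem_period", "regime_span"):
        lo, hi = getattr(cfg, name)
        if lo < span[0] or hi > span[1]:
            raise ValueError(f"{name} {[lo, hi]} outside data span {list(span)}")

    # --- ring series: BAI, RCS, chronology, EPS -----------------------
    bai = [rings.to_bai(t) for t in trees]
    curve = rings.build_regional_curve(bai, cfg.min_trees, cfg.smooth_window)
    residuals = rings.rcs_detrend(bai, curve)
    chronology = rings.build_chronology(residuals)
    overlap = (max(t.first_year for t in trees), span[1])
    eps_value, rbar, n_trees = rings.eps(trees, overlap)

    # --- physiology ---------------------------------------------------
    constants = FractionationConstants()
    per_tree_phys, phys_chron = derive_physiology(isotopes, environment, constants)

    # --- climatic water balance ---------------------------------------
    season = {
        var: climate_mod.seasonal_mean(climate, var, cfg.season_months)
        for var in ("tmax", "prcp", "vpdmax", "wbal")
    }
    wbal_z = climate_mod.zscore(season["wbal"])

    # --- climate response ---------------------------------------------
    lo, hi = cfg.correlation_period
    chron_period = chronology["value"][
        (chronology.index >= lo) & (chronology.index <= hi)
    ]
    corr_fn = response.correlation_function(
        chron_period,
        climate,
        variables=["tmax", "prcp", "wbal"],
        n_boot=cfg.n_boot,
        alpha=cfg.alpha,
        seed=cfg.seed,
    )
    ring_series = {
        "bai": chron_period,
        "delta13c": phys_chron["delta13c"],
        "iwue": phys_chron["iwue"],
        "d18o": phys_chron["d18o"],
    }
    clip = lambda s: s[(s.index >= lo) & (s.index <= hi)]
    table1 = response.table1_analog(
        {k: clip(v) for k, v in ring_series.items()},
        {k: clip(v) for k, v in season.items()},
    )

    # --- piecewise SEM ------------------------------------------------
    sem_results = {}
    sem_lo, sem_hi = cfg.sem_period
    resid_long = (
        pd.concat(residuals, names=["tree_id", "year"]).rename("bai").reset_index()
    )
    sem_base = per_tree_phys.merge(resid_long, on=["tree_id", "year"], how="inner")
    env_cols = environment.rename(
        columns={"co2_ppm": "co2", "so4_dep": "so4"}
    )[["year", "co2", "so4", "n_dep"]]
    sem_base = sem_base.merge(env_cols, on="year")
    sem_base = sem_base.merge(
        season["wbal"].rename("wbal").reset_index(), on="year"
    )
    sem_base = sem_base[(sem_base["year"] >= sem_lo) & (sem_base["year"] <= sem_hi)]
    for gas in cfg.sem_gas_exchange:
        spec = synthetic.default_sem_spec(gas)
        sem_results[gas] = sem.fit_sem(spec, sem_base)

    # --- regime shift -------------------------------------------------
    rlo, rhi = cfg.regime_span
    wz = wbal_z[(wbal_z.index >= rlo) & (wbal_z.index <= rhi)]
    cp = regime.pettitt(wz)
    comparisons = {"wbal": regime.compare_periods(wz, cp.change_year)}
    for name, series in ring_series.items():
        s = series[(series.index >= rlo) & (series.index <= rhi)].dropna()
        comparisons[name] = regime.compare_periods(s, cp.change_year)

    manifest = {
        "config_hash": _config_hash(cfg),
        "package_version": _version(),
        "seed": cfg.seed,
        "n_trees": len(trees),
        "n_isotope_trees": int(isotopes["tree_id"].nunique()),
        "rows": {
            "climate": len(climate),
            "isotopes": len(isotopes),
            "sem": len(sem_base),
        },
        "eps": {"value": eps_value, "rbar": rbar, "n": n_trees},
        "warnings": warnings_count,
        "elapsed_s": round(time.time() - t0, 2),
        "fractionation": dataclasses.asdict(constants),
    }

    results = {
        "study": study,
        "trees": trees,
        "chronology": chronology,
        "regional_curve": curve,
        "eps": (eps_value, rbar, n_trees),
        "physiology": per_tree_phys,
        "physiology_chronology": phys_chron,
        "seasonal": season,
        "wbal_z": wbal_z,
        "correlation_function": corr_fn,
        "table1": table1,
        "sem": sem_results,
        "sem_data": sem_base,
        "change_point": cp,
        "comparisons": comparisons,
        "manifest": manifest,
    }
    if out_dir is not None:
        _write_outputs(results, cfg, Path(out_dir))
    return results


def _version() -> str:
    from importlib.metadata import PackageNotFoundError, version

    try:
        return version("dendrosem")
    except PackageNotFoundError:
        return "unknown"


def _write_outputs(results: dict, cfg: PipelineConfig, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    results["chronology"].to_csv(out_dir / "chronology.csv")
    results["physiology"].to_csv(out_dir / "physiology_per_tree.csv", index=False)
    results["physiology_chronology"].to_csv(out_dir / "physiology_chronology.csv")
    results["correlation_function"].to_csv(out_dir / "correlation_function.csv", index=False)
    results["table1"].to_csv(out_dir / "table1_analog.csv", index=False)
    for gas, fit in results["sem"].items():
        fit.paths.to_csv(out_dir / f"sem_paths_{gas}.csv", index=False)
        fit.claims.to_csv(out_dir / f"sem_claims_{gas}.csv", index=False)
        (out_dir / f"sem_summary_{gas}.json").write_text(
            json.dumps(fit.summary(), indent=2)
        )
    cp = results["change_point"]
    regime_rows = []
    for name, comp in results["comparisons"].items():
        regime_rows.append(
            {
                "series": name,
                "split_year": comp.split_year,
                "mean_before": comp.mean_before,
                "mean_after": comp.mean_after,
                "ks_D": comp.ks_D,
                "ks_p": comp.ks_p,
                "sen_slope_before": comp.trend_before.sen_slope,
                "mk_p_before": comp.trend_before.mk_p,
                "sen_slope_after": comp.trend_after.sen_slope,
                "mk_p_after": comp.trend_after.mk_p,
                "sen_slope_overall": comp.trend_overall.sen_slope,
                "mk_p_overall": comp.trend_overall.mk_p,
            }
        )
    pd.DataFrame(regime_rows).to_csv(out_dir / "regime_shift.csv", index=False)
    summary = {
        "change_point": {"year": cp.change_year, "K": cp.K, "p": cp.p},
        "eps": results["manifest"]["eps"],
    }
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2))
    (out_dir / "manifest.json").write_text(json.dumps(results["manifest"], indent=2))
    with open(out_dir / "config_echo.yml", "w") as fh:
        yaml.safe_dump(dataclasses.asdict(cfg), fh, sort_keys=True)
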