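"""Synthetic forest studies with recorded ground truth.

Generates everything the analysis pipeline consumes — monthly climate,
annual environmental drivers (CO2, atmospheric delta13C, SO4 and N
deposition), per-tree ring widths, and per-tree latewood isotope series —
from a small set of generative parameters, so every downstream stage can
be tested against known truth.

The study emulated: a temperate mesic broadleaf stand at ~41.4 N with 15
trees per species over 1895-2014, a moisture regime shift (dry -> wet) in
the summer water balance after 1983, monotone CO2 rise with the Suess
decline in atmospheric delta13C, and acid/N deposition that rises to a
peak and then declines. Growth is multiplicative in BAI space: an
age-dependent (Hugershoff-form) ontogenetic curve times a lognormal
response to the standardized summer water balance, a per-tree random
effect, and noise; ring widths are back-computed from cumulative basal
area. Isotopes are generated through the inverse of the discrimination
chain so that the forward physiology recovers the planted ci/ca exactly
when noise is zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import climate as climate_mod
from .isotopes import FractionationConstants, ring_d13c_from_discrimination
from .rings import TreeRingSeries
from .sem import SEMSpec

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "SyntheticStudy",
    "GenerationError",
    "generate_climate",
    "generate_environment",
    "generate_trees",
    "generate_isotopes",
    "generate_study",
    "write_study",
    "default_sem_spec",
    "simulate_sem_dataset",
]

JJA = (6, 7, 8)

# named sub-streams fanned out from the master seed
_CHANNELS = {"climate": 0, "environment": 1, "trees": 2, "isotopes": 3}


class GenerationError(RuntimeError):
    pass


@dataclass
class SyntheticConfig:
    """Generative parameters of a synthetic two-regime forest study."""

    # study design
    year_range: tuple[int, int] = (1895, 2014)
    n_trees: int = 15
    recruit_year_range: tuple[int, int] = (1895, 1915)
    latitude: float = 41.4
    change_point_year: int = 1983  # last dry year; wet regime starts the year after
    wet_shift: float = 1.0  # SDs of the summer water balance

    # climate model
    temp_base: float = 9.5  # deg C annual mean
    temp_amplitude: float = 12.0  # deg C seasonal half-range, peak in July
    warming_trend: float = 0.01  # deg C per year
    temp_noise_sd: float = 1.2  # deg C on monthly means
    diurnal_range: float = 10.5  # deg C tmax - tmin
    diurnal_range_sd: float = 0.8
    prcp_monthly_mean: float = 100.0  # mm/month climatology level
    prcp_seasonal_amplitude: float = 10.0  # mm/month, peak in July
    prcp_log_sd: float = 0.45  # lognormal dispersion of monthly precipitation
    vpd_noise_sd: float = 1.0  # hPa

    # environmental drivers
    co2_start: float = 290.0  # ppm at the first year
    co2_end: float = 400.0  # ppm at the last year
    d13c_atm_start: float = -6.5  # permil
    d13c_atm_end: float = -8.5
    so4_start: float = 12.0  # kg/ha water-year wet deposition
    so4_peak: float = 35.0
    so4_peak_year: int = 1972
    so4_end: float = 8.0
    n_start: float = 2.5
    n_peak: float = 7.0
    n_peak_year: int = 1990
    n_end: float = 4.0
    # interannual variability of water-year wet deposition is precipitation
    # driven and large (~15-25% CV in monitoring records)
    deposition_noise_sd: float = 0.15  # lognormal sd on deposition

    # growth model: g(a) = c * a^p * exp(-q a) + d, mm^2 per year of cambial age
    growth_curve: tuple[float, float, float, float] = (150.0, 0.7, 0.02, 50.0)
    beta_water: float = 0.3  # log-BAI response per SD of summer water balance
    sigma_tree: float = 0.15  # SD of per-tree lognormal random effect
    sigma_growth_noise: float = 0.25  # SD of lognormal year-to-year noise

    # ci/ca model (dimensionless)
    cica_base: float = 0.65
    gamma_water: float = 0.02  # per SD of summer water balance
    gamma_co2: float = 0.0001  # per ppm of CO2 above the first year
    cica_tree_sd: float = 0.01
    cica_noise_sd: float = 0.025

    # d18O model (permil)
    o18_base: float = 28.0
    kappa_water: float = 0.5  # per SD of summer water balance (enters negatively)
    kappa_source: float = 1.0  # loading on the source-water anomaly
    source_water_slope: float = -0.01  # permil/yr decline of source-water d18O
    o18_tree_sd: float = 0.25
    o18_noise_sd: float = 0.35

    # isotope subsample (a subset of trees, as in a latewood cellulose campaign)
    n_isotope_trees: int = 5
    isotope_year_range: tuple[int, int] = (1950, 2014)

    seed: int = 0

    def __post_init__(self):
        y0, y1 = self.year_range
        if y1 - y0 + 1 < 40:
            raise ValueError("year_range must span >= 40 years")
        if self.n_trees < 2:
            raise ValueError("n_trees must be >= 2")
        if not (y0 < self.change_point_year < y1):
            raise ValueError("change_point_year must lie strictly inside year_range")
        r0, r1 = self.recruit_year_range
        if not (y0 <= r0 <= r1 <= y1):
            raise ValueError("recruit_year_range must lie inside year_range")
        for name in (
            "temp_noise_sd", "diurnal_range_sd", "prcp_log_sd", "vpd_noise_sd",
            "deposition_noise_sd", "sigma_tree", "sigma_growth_noise",
            "cica_tree_sd", "cica_noise_sd", "o18_tree_sd", "o18_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_isotope_trees > self.n_trees:
            raise ValueError("n_isotope_trees cannot exceed n_trees")
        c, p, q, d = self.growth_curve
        ages = np.arange(1, 401)
        if np.any(c * ages**p * np.exp(-q * ages) + d <= 0):
            raise ValueError("growth curve must be positive at all ages")
        # ci/ca must stay inside (0, 1) at +-4 SD of its inputs
        dco2 = self.co2_end - self.co2_start
        spread = (
            4.0 * abs(self.gamma_water)
            + abs(self.gamma_co2) * dco2
            + 4.0 * (self.cica_tree_sd + self.cica_noise_sd)
        )
        if not (0.0 < self.cica_base - spread and self.cica_base + spread < 1.0):
            raise ValueError("ci/ca parameters can leave (0, 1) within +-4 SD of inputs")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.year_range[0], self.year_range[1] + 1)

    def rng(self, channel: str) -> np.random.Generator:
        """Named sub-stream of the master seed (bit-for-bit reproducible)."""
        key = _CHANNELS[channel]
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(key,)))


@dataclass
class SyntheticTruth:
    """Everything needed to score recovery: parameters and realized latents."""

    config: SyntheticConfig
    change_point_year: int
    tree_effects: dict[str, float]
    recruit_years: dict[str, int]
    water_anomaly: pd.Series  # standardized JJA water balance, by year
    cica_tree_offsets: dict[str, float] = field(default_factory=dict)
    o18_tree_offsets: dict[str, float] = field(default_factory=dict)


@dataclass
class SyntheticStudy:
    config: SyntheticConfig
    climate: pd.DataFrame  # monthly, with pet and wbal
    environment: pd.DataFrame  # annual drivers
    trees: list[TreeRingSeries]
    isotopes: pd.DataFrame  # tree_id, year, d13c, d18o
    truth: SyntheticTruth


def _monthly_climatology(config: SyntheticConfig, month: np.ndarray):
    phase = np.cos(2.0 * np.pi * (month - 7) / 12.0)
    tmean = config.temp_base + config.temp_amplitude * phase
    prcp = config.prcp_monthly_mean + config.prcp_seasonal_amplitude * phase
    return tmean, prcp


def summer_shift_mm(config: SyntheticConfig) -> float:
    """Additive JJA precipitation shift (mm/month) equal to `wet_shift` SDs
    of the pre-shift seasonal water-balance mean (precipitation component)."""
    _, clim = _monthly_climatology(config, np.array(JJA))
    var_season = np.sum(clim**2 * (np.exp(config.prcp_log_sd**2) - 1.0)) / 9.0
    return config.wet_shift * float(np.sqrt(var_season))


def generate_climate(config: SyntheticConfig) -> pd.DataFrame:
    """Monthly climate table with tmin, tmax, prcp, vpdmax, pet, wbal.

    Temperature is a seasonal sinusoid plus a linear warming trend and
    Gaussian noise; precipitation is lognormal (mean-corrected) around a
    monthly climatology, with the wet-regime shift added to June-August
    precipitation in every year after the change point.
    """
    rng = config.rng("climate")
    years = config.years
    yy, mm = np.meshgrid(years, np.arange(1, 13), indexing="ij")
    yy, mm = yy.ravel(), mm.ravel()
    tmean_clim, prcp_clim = _monthly_climatology(config, mm)
    tmean = (
        tmean_clim
        + config.warming_trend * (yy - years[0])
        + rng.normal(0.0, config.temp_noise_sd, size=yy.shape)
    )
    drange = np.maximum(
        2.0, config.diurnal_range + rng.normal(0.0, config.diurnal_range_sd, size=yy.shape)
    )
    tmin = tmean - drange / 2.0
    tmax = tmean + drange / 2.0
    z = rng.normal(0.0, 1.0, size=yy.shape)
    prcp = prcp_clim * np.exp(config.prcp_log_sd * z - config.prcp_log_sd**2 / 2.0)
    wet = (yy > config.change_point_year) & np.isin(mm, JJA)
    prcp = prcp + wet * summer_shift_mm(config)
    # max VPD: warm, dry months are more evaporative
    vpd = np.maximum(
        1.0,
        0.9 * tmax
        + 4.0
        - 0.03 * (prcp - prcp_clim)
        + rng.normal(0.0, config.vpd_noise_sd, size=yy.shape),
    )
    table = pd.DataFrame(
        {"year": yy, "month": mm, "tmin": tmin, "tmax": tmax, "prcp": prcp, "vpdmax": vpd}
    )
    return climate_mod.water_balance(table, config.latitude)


def _rise_fall(years: np.ndarray, y0_val, peak_year, peak_val, yend_val) -> np.ndarray:
    """Piecewise-linear rise to a peak year then decline (degenerate peaks allowed)."""
    y0, y1 = years[0], years[-1]
    peak_year = min(max(peak_year, y0), y1)
    out = np.empty(len(years), dtype=float)
    up = years <= peak_year
    if peak_year > y0:
        out[up] = y0_val + (peak_val - y0_val) * (years[up] - y0) / (peak_year - y0)
    else:
        out[up] = peak_val
    if peak_year < y1:
        out[~up] = peak_val + (yend_val - peak_val) * (years[~up] - peak_year) / (y1 - peak_year)
    return out


def generate_environment(config: SyntheticConfig) -> pd.DataFrame:
    """Annual drivers: CO2 (ppm), atmospheric d13C (permil), SO4 and N
    wet deposition (kg/ha, water-year totals).

    CO2 is an exponential-plus-offset curve (strictly increasing);
    atmospheric d13C declines linearly (the Suess effect); deposition is
    a piecewise-linear rise to a peak year then decline, with lognormal
    noise, floored at zero.
    """
    rng = config.rng("environment")
    years = config.years
    n = len(years)
    growth = np.log((config.co2_end - 280.0) / (config.co2_start - 280.0)) / (n - 1)
    co2 = 280.0 + (config.co2_start - 280.0) * np.exp(growth * np.arange(n))
    d13c_atm = np.linspace(config.d13c_atm_start, config.d13c_atm_end, n)
    so4 = _rise_fall(years, config.so4_start, config.so4_peak_year, config.so4_peak, config.so4_end)
    ndep = _rise_fall(years, config.n_start, config.n_peak_year, config.n_peak, config.n_end)
    if config.deposition_noise_sd > 0:
        so4 = so4 * rng.lognormal(0.0, config.deposition_noise_sd, n)
        ndep = ndep * rng.lognormal(0.0, config.deposition_noise_sd, n)
    return pd.DataFrame(
        {
            "year": years,
            "co2_ppm": co2,
            "d13c_atm": d13c_atm,
            "so4_dep": np.maximum(so4, 0.0),
            "n_dep": np.maximum(ndep, 0.0),
        }
    )


def water_anomaly(config: SyntheticConfig, climate: pd.DataFrame) -> pd.Series:
    """Standardized summer (JJA) water balance of a generated climate."""
    seasonal = climate_mod.seasonal_mean(climate, "wbal", months=JJA)
    return climate_mod.zscore(seasonal)


def _growth_curve(config: SyntheticConfig, ages: np.ndarray) -> np.ndarray:
    c, p, q, d = config.growth_curve
    g = c * ages.astype(float) ** p * np.exp(-q * ages) + d
    if np.any(g <= 0):
        raise ValueError("growth curve non-positive at a needed age")
    return g


def generate_trees(
    config: SyntheticConfig, climate: pd.DataFrame
) -> tuple[list[TreeRingSeries], SyntheticTruth]:
    """Per-tree ring-width series plus the ground truth that produced them.

    BAI_{i,t} = g(age) * exp(beta_water * W_t + u_i + eps_{i,t}); ring
    widths are back-computed from cumulative basal area, so the growth
    model is exact in BAI space.
    """
    rng = config.rng("trees")
    anomaly = water_anomaly(config, climate)
    y0, y1 = config.year_range
    if anomaly.index.min() > y0 or anomaly.index.max() < y1:
        raise ValueError("climate does not cover all tree lifespans")
    r0, r1 = config.recruit_year_range
    recruit = rng.integers(r0, r1 + 1, size=config.n_trees)
    u = rng.normal(0.0, config.sigma_tree, size=config.n_trees)
    trees = []
    tree_effects, recruit_years = {}, {}
    for i in range(config.n_trees):
        tid = f"T{i + 1:03d}"
        years = np.arange(recruit[i], y1 + 1)
        ages = np.arange(1, len(years) + 1)
        w = anomaly.reindex(years).to_numpy()
        eps = rng.normal(0.0, config.sigma_growth_noise, size=len(years))
        bai = _growth_curve(config, ages) * np.exp(config.beta_water * w + u[i] + eps)
        radius = np.sqrt(np.cumsum(bai) / np.pi)
        widths = np.diff(np.concatenate([[0.0], radius]))
        trees.append(TreeRingSeries(tree_id=tid, first_year=int(years[0]), widths=widths))
        tree_effects[tid] = float(u[i])
        recruit_years[tid] = int(years[0])
    truth = SyntheticTruth(
        config=config,
        change_point_year=config.change_point_year,
        tree_effects=tree_effects,
        recruit_years=recruit_years,
        water_anomaly=anomaly,
    )
    return trees, truth


def generate_isotopes(
    config: SyntheticConfig,
    climate: pd.DataFrame,
    environment: pd.DataFrame,
    truth: SyntheticTruth,
    constants: FractionationConstants = FractionationConstants(),
) -> pd.DataFrame:
    """Per-tree latewood d13C and d18O tables for the isotope subsample.

    ci/ca is linear in the water anomaly and the CO2 increment; the ring
    d13C is the exact inverse of the discrimination equations, so forward
    physiology recovers the planted ci/ca (exactly at zero noise). d18O
    decreases with the water anomaly and tracks a declining source-water
    signature.
    """
    rng = config.rng("isotopes")
    anomaly = truth.water_anomaly
    env = environment.set_index("year")
    iso_ids = sorted(truth.recruit_years)[: config.n_isotope_trees]
    lo = max(config.isotope_year_range[0], config.year_range[0])
    hi = min(config.isotope_year_range[1], config.year_range[1])
    cica_off = rng.normal(0.0, config.cica_tree_sd, size=len(iso_ids))
    o18_off = rng.normal(0.0, config.o18_tree_sd, size=len(iso_ids))
    rows = []
    for i, tid in enumerate(iso_ids):
        years = np.arange(max(lo, truth.recruit_years[tid]), hi + 1)
        w = anomaly.reindex(years).to_numpy()
        dco2 = env["co2_ppm"].reindex(years).to_numpy() - float(
            env["co2_ppm"].loc[config.year_range[0]]
        )
        cica = (
            config.cica_base
            + config.gamma_water * w
            + config.gamma_co2 * dco2
            + cica_off[i]
            + rng.normal(0.0, config.cica_noise_sd, size=len(years))
        )
        bad = (cica <= 0) | (cica >= 1)
        if bad.any():
            raise GenerationError(
                f"ci/ca outside (0, 1) for tree {tid} in years {list(years[bad])}"
            )
        delta = constants.a + (constants.b - constants.a) * cica
        d13c = ring_d13c_from_discrimination(delta, env["d13c_atm"].reindex(years).to_numpy())
        source = config.source_water_slope * (years - config.year_range[0])
        d18o = (
            config.o18_base
            - config.kappa_water * w
            + config.kappa_source * source
            + o18_off[i]
            + rng.normal(0.0, config.o18_noise_sd, size=len(years))
        )
        rows.append(
            pd.DataFrame({"tree_id": tid, "year": years, "d13c": d13c, "d18o": d18o})
        )
        truth.cica_tree_offsets[tid] = float(cica_off[i])
        truth.o18_tree_offsets[tid] = float(o18_off[i])
    return pd.concat(rows, ignore_index=True)


def generate_study(config: SyntheticConfig) -> SyntheticStudy:
    """Run all four generators off one master seed."""
    clim = generate_climate(config)
    env = generate_environment(config)
    trees, truth = generate_trees(config, clim)
    iso = generate_isotopes(config, clim, env, truth)
    return SyntheticStudy(
        config=config, climate=clim, environment=env, trees=trees, isotopes=iso, truth=truth
    )


def write_study(study: SyntheticStudy, outdir) -> dict[str, str]:
    """Write the study as the pipeline's plain-text input contracts."""
    from pathlib import Path

    import yaml

    from .rwl import write_rwl

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "rwl": outdir / "rings.rwl",
        "climate": outdir / "climate.csv",
        "environment": outdir / "environment.csv",
        "isotopes": outdir / "isotopes.csv",
        "truth": outdir / "truth.yml",
    }
    write_rwl(study.trees, paths["rwl"])
    study.climate.to_csv(paths["climate"], index=False)
    study.environment.to_csv(paths["environment"], index=False)
    study.isotopes.to_csv(paths["isotopes"], index=False)
    truth = study.truth
    payload = {
        "config": asdict(truth.config),
        "change_point_year": truth.change_point_year,
        "tree_effects": truth.tree_effects,
        "recruit_years": truth.recruit_years,
        "cica_tree_offsets": truth.cica_tree_offsets,
        "o18_tree_offsets": truth.o18_tree_offsets,
        "water_anomaly": {int(k): float(v) for k, v in truth.water_anomaly.items()},
    }
    with open(paths["truth"], "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)
    return {k: str(v) for k, v in paths.items()}


def default_sem_spec(gas_exchange: str = "delta13c", group: str = "tree_id") -> SEMSpec:
    """The path diagram the pipeline fits: four environmental drivers,
    three tree responses, free covariation among driver pairs and among
    response residuals (double-headed arrows)."""
    if gas_exchange not in ("delta13c", "iwue"):
        raise ValueError("gas_exchange must be 'delta13c' or 'iwue'")
    g = gas_exchange
    return SEMSpec(
        exogenous=["wbal", "co2", "so4", "n_dep"],
        endogenous=[g, "d18o", "bai"],
        edges=[
            ("wbal", g), ("co2", g), ("so4", g), ("n_dep", g),
            ("wbal", "d18o"), ("so4", "d18o"), ("n_dep", "d18o"),
            ("wbal", "bai"), ("co2", "bai"), ("n_dep", "bai"),
        ],
        correlated_errors=[(g, "d18o"), (g, "bai"), ("d18o", "bai")],
        group=group,
    )


#: true structural coefficients used by :func:`simulate_sem_dataset`
DEFAULT_SEM_COEFS: dict[tuple[str, str], float] = {
    ("wbal", "delta13c"): 0.5,
    ("co2", "delta13c"): 0.15,
    ("so4", "delta13c"): -0.10,
    ("n_dep", "delta13c"): 0.10,
    ("wbal", "d18o"): -0.5,
    ("so4", "d18o"): 0.15,
    ("n_dep", "d18o"): -0.10,
    ("wbal", "bai"): 0.4,
    ("co2", "bai"): 0.10,
    ("n_dep", "bai"): 0.10,
}


def simulate_sem_dataset(
    n_trees: int = 5,
    years: tuple[int, int] = (1981, 2014),
    coefs: dict[tuple[str, str], float] | None = None,
    sigma_tree: float = 0.4,
    sigma_resid: float = 0.8,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Linear-Gaussian data generated exactly from the default path diagram.

    Exogenous drivers are unit-variance annual series (CO2 and deposition
    correlated with each other, the water balance independent of them);
    each endogenous response adds its structural parents, a per-tree
    random intercept, and iid noise. Used for SEM calibration: d-sep
    claims hold in the generating model, so Fisher's C should be well
    calibrated, and every path coefficient is known.
    """
    if coefs is None:
        coefs = DEFAULT_SEM_COEFS
    rng = np.random.default_rng(seed)
    yrs = np.arange(years[0], years[1] + 1)
    n_years = len(yrs)
    cov = np.array(
        [
            [1.0, -0.5, 0.4],
            [-0.5, 1.0, 0.3],
            [0.4, 0.3, 1.0],
        ]
    )  # co2, so4, n_dep
    drivers = rng.multivariate_normal(np.zeros(3), cov, size=n_years)
    exog = pd.DataFrame(
        {
            "year": yrs,
            "wbal": rng.normal(0.0, 1.0, n_years),
            "co2": drivers[:, 0],
            "so4": drivers[:, 1],
            "n_dep": drivers[:, 2],
        }
    )
    responses = ["delta13c", "d18o", "bai"]
    u = {r: rng.normal(0.0, sigma_tree, n_trees) for r in responses}
    frames = []
    for i in range(n_trees):
        df = exog.copy()
        df["tree_id"] = f"T{i + 1:03d}"
        for r in responses:
            mean = sum(
                b * df[src].to_numpy() for (src, dst), b in coefs.items() if dst == r
            )
            df[r] = mean + u[r][i] + rng.normal(0.0, sigma_resid, n_years)
        frames.append(df)
    data = pd.concat(frames, ignore_index=True)
    truth = {
        "coefs": dict(coefs),
        "sigma_tree": sigma_tree,
        "sigma_resid": sigma_resid,
        "n_trees": n_trees,
        "years": years,
    }
    return data, truth
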