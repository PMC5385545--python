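"""Shared study definitions for the numbered analysis drivers.

Two synthetic species share the same climate forcing (same master seed for
the climate channel is not enforced; each stand carries its own weather
realization of the same regime) but differ in ontogenetic growth rate and
stand seed.
"""

from pathlib import Path

import pandas as pd

from dendrosem import synthetic
from dendrosem.rwl import read_rwl

ROOT = Path(__file__).resolve().parents[1]
STUDY_DIR = ROOT / "scratch" / "study"
RESULTS_DIR = ROOT / "results"

SPECIES = {
    # fast-growing lowland broadleaf
    "species_a": synthetic.SyntheticConfig(seed=11),
    # slower ridge oak: lower asymptotic growth, slightly tighter water coupling
    "species_b": synthetic.SyntheticConfig(
        seed=12, growth_curve=(110.0, 0.65, 0.015, 40.0), beta_water=0.25
    ),
}


def load_study(name: str):
    base = STUDY_DIR / name
    if not base.exists():
        raise SystemExit(f"{base} missing - run analysis/01_simulate.py first")
    return {
        "trees": read_rwl(base / "rings.rwl"),
        "climate": pd.read_csv(base / "climate.csv"),
        "environment": pd.read_csv(base / "environment.csv"),
        "isotopes": pd.read_csv(base / "isotopes.csv"),
        "config": SPECIES[name],
    }


def ensure_results() -> Path:
    RESULTS_DIR.mkdir(exist_ok=True)
    return RESULTS_DIR
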