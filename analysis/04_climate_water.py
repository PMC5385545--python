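#!/usr/bin/env python
"""Compute the summer (JJA) climatic water balance from each stand's monthly
climate, standardize it, and locate the moisture regime change point.

Writes results/summer_water_balance_<species>.csv.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import SPECIES, ensure_results, load_study  # noqa: E402

from dendrosem import climate as cm  # noqa: E402
from dendrosem import regime  # noqa: E402


def main() -> None:
    results = ensure_results()
    for name, cfg in SPECIES.items():
        data = load_study(name)
        clim = data["climate"]
        season = cm.seasonal_mean(clim, "wbal")
        z = cm.zscore(season)
        z.rename("wbal_z").to_csv(results / f"summer_water_balance_{name}.csv")
        cp = regime.pettitt(z)
        print(
            f"{name}: JJA water balance mean {season.mean():.0f} mm/month; "
            f"Pettitt change point {cp.change_year} (planted {cfg.change_point_year}), "
            f"K = {cp.K:.0f}, p = {cp.p:.2g}; "
            f"segment means {cp.mean_before:+.2f} -> {cp.mean_after:+.2f} SD"
        )


if __name__ == "__main__":
    main()
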