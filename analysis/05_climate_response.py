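#!/usr/bin/env python
"""Climate-response screening: bootstrapped monthly correlation functions of
the residual-BAI chronology, and the prewhitened summer cross table between
tree-ring variables (BAI, Delta13C, iWUE, d18O) and climate (Tmax,
precipitation, VPDmax, water balance) for 1950-2014.

Writes results/correlation_function_<species>.csv and
results/summer_correlations_<species>.csv.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import SPECIES, ensure_results, load_study  # noqa: E402

from dendrosem import climate as cm  # noqa: E402
from dendrosem import response  # noqa: E402
from dendrosem.isotopes import derive_physiology  # noqa: E402

PERIOD = (1950, 2014)


def main() -> None:
    results = ensure_results()
    for name, cfg in SPECIES.items():
        data = load_study(name)
        chron = pd.read_csv(results / f"chronology_{name}.csv", index_col="year")["value"]
        _, phys = derive_physiology(data["isotopes"], data["environment"])
        clip = lambda s: s[(s.index >= PERIOD[0]) & (s.index <= PERIOD[1])].dropna()

        corr_fn = response.correlation_function(
            clip(chron), data["climate"], ["tmax", "prcp", "wbal"],
            n_boot=1000, seed=cfg.seed,
        )
        corr_fn.to_csv(results / f"correlation_function_{name}.csv", index=False)
        sig = corr_fn[corr_fn["significant"]]
        strongest = corr_fn.loc[corr_fn["r"].abs().idxmax()]
        print(
            f"{name}: {len(sig)}/{len(corr_fn)} significant month cells; strongest "
            f"|r| = {strongest['r']:+.2f} for {strongest['variable']} in "
            f"{strongest['month']}"
        )

        season = {
            var: clip(cm.seasonal_mean(data["climate"], var))
            for var in ("tmax", "prcp", "vpdmax", "wbal")
        }
        table = response.table1_analog(
            {
                "bai": clip(chron),
                "delta13c": clip(phys["delta13c"]),
                "iwue": clip(phys["iwue"]),
                "d18o": clip(phys["d18o"]),
            },
            season,
        )
        table.to_csv(results / f"summer_correlations_{name}.csv", index=False)
        wb = table[table["climate"] == "wbal"].set_index("treering")
        print(
            "  summer water-balance correlations: "
            + ", ".join(f"{v} {wb.loc[v, 'r']:+.2f}{wb.loc[v, 'stars']}" for v in wb.index)
        )


if __name__ == "__main__":
    main()
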