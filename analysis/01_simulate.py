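#!/usr/bin/env python
"""Simulate the two-species study: 15 trees per species over 1895-2014 with a
dry-to-wet summer water-balance shift after 1983, rising CO2, declining
atmospheric delta13C, and rise-then-decline SO4/N deposition.

Species A emulates a fast-growing lowland broadleaf (tulip-poplar-like),
species B a slower ridge oak. Writes RWL + CSV inputs and the generative
truth under scratch/study/<species>/ for the downstream stages.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "analysis"))
from common import SPECIES, STUDY_DIR  # noqa: E402

from dendrosem import synthetic  # noqa: E402


def main() -> None:
    for name, cfg in SPECIES.items():
        study = synthetic.generate_study(cfg)
        paths = synthetic.write_study(study, STUDY_DIR / name)
        w = study.truth.water_anomaly
        post = w[w.index > cfg.change_point_year].mean()
        pre = w[w.index <= cfg.change_point_year].mean()
        print(
            f"{name}: {cfg.n_trees} trees, {cfg.year_range[0]}-{cfg.year_range[1]}; "
            f"summer water anomaly shifts {post - pre:+.2f} SD after "
            f"{cfg.change_point_year}; wrote {len(paths)} files to {STUDY_DIR / name}"
        )


if __name__ == "__main__":
    main()
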