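# dendrosem

Attribution of tree radial growth and leaf gas exchange to water
availability versus rising CO2 and acid/nitrogen deposition, from tree-ring
widths and stable isotopes — as a tested, reusable Python pipeline with a
synthetic-forest generator for ground-truth validation.

## Who this is for

Dendroecologists and ecophysiologists who have (or want to simulate) a
stand-level data set of:

- ring-width series (Tucson/RWL format, mm),
- per-tree annual latewood δ13C and δ18O (‰),
- monthly climate (Tmin, Tmax, precipitation, optionally VPDmax),
- annual atmospheric CO2 (ppm), atmospheric δ13C (‰), and SO4/N wet
  deposition (kg ha⁻¹, water-year totals),

and who want to ask: *is moisture, CO2, or deposition driving growth and
gas exchange?*

## The methods at the core

- **Growth**: ring widths → basal area increment BAIₜ = π(r²ₜ − r²ₜ₋₁);
  age trends removed by Regional Curve Standardization (divide each tree by
  the stand's mean BAI-at-cambial-age curve); chronology quality by the
  expressed population signal EPS = n·r̄/(n·r̄ + 1 − r̄).
- **Physiology**: Δ13C = (δ¹³C_atm − δ¹³C_ring)/(1 + δ¹³C_ring/1000);
  ci/ca = (Δ − a)/(b − a) with a = 4.4‰, b = 27‰;
  iWUE = ca·(1 − ci/ca)·0.625 (μmol mol⁻¹).
- **Moisture**: monthly climatic water balance W = P − PET with Hargreaves
  PET (FAO-56 extraterrestrial radiation at mid-month), summarized as the
  standardized June–August mean.
- **Climate response**: bootstrapped monthly correlation functions (years
  resampled, percentile CIs) and prewhitened (AR(1)-removed) seasonal
  Pearson correlations.
- **Joint attribution**: piecewise structural equation models — each
  response (residual BAI, Δ13C or iWUE, δ18O) gets a linear mixed model
  with a tree-level random intercept fit by REML (implemented here, profiled
  variance ratio); global fit by d-separation with Fisher's
  C = −2Σln pᵢ ~ χ²(2k), plus AICc and marginal/conditional R².
- **Regime shift**: Pettitt change point, Mann-Kendall + Theil-Sen trends,
  and dry-vs-wet two-sample Kolmogorov–Smirnov comparisons.

A synthetic forest generator (`dendrosem.synthetic`) produces complete
studies — climate with a planted dry→wet summer shift, monotone CO2 and
Suess-effect δ13C_atm, rise-then-decline deposition, trees grown as
g(age)·exp(β_w·W̃ + uᵢ + ε), and isotopes generated by exact inversion of
the discrimination chain — with every generative parameter recorded, so
each stage is testable against known truth.

## Worked example

```sh
python analysis/01_simulate.py      # two 15-tree stands, 1895-2014
python analysis/02_detrend.py      # BAI, RCS, chronology, EPS
python analysis/03_physiology.py   # Δ13C, ci/ca, iWUE
python analysis/04_climate_water.py
python analysis/05_climate_response.py
python analysis/06_sem.py
python analysis/07_regime_shift.py
```

Representative output (species A):

```
species_a: 15 trees, common period 1915-2014, rbar = 0.72, EPS = 0.974 (adequate)
species_a: JJA water balance mean -29 mm/month; Pettitt change point 1983
  (planted 1983), K = 1821, p = 2.2e-05; segment means -0.31 -> +0.88 SD
summer water-balance correlations: bai +0.86***, delta13c +0.87***,
  iwue -0.54***, d18o -0.93***
species_a/delta13c: C = 6.72 (df 4, p = 0.152), AICc = 49.8, n = 170
  bai:      strongest path wbal (+0.68, p = 5.5e-22)
  d18o:     strongest path wbal (-0.76, p = 5.5e-36)
  delta13c: strongest path wbal (+0.45, p = 5.9e-11)
```

Reading: the chronology carries a strong common signal (EPS ≥ 0.85
adequacy threshold); the summer water balance shifted to a wetter regime
after 1983 and is detected there; wetter summers raise discrimination
(stomata open, Δ13C–W positive) and growth, lower iWUE and δ18O; and when
water balance, CO2, and SO4/N deposition compete in the same SEM, the
water-balance path is the largest standardized path into every response,
while the model's d-separation claims are not rejected (global p = 0.15).
In the iWUE-based SEM variant the CO2 path into iWUE can rival the water
path because ca enters iWUE's definition directly.

The same pipeline runs on real inputs via the CLI:

```sh
dendrosem simulate --out study/ --seed 1     # or bring your own files
dendrosem run --config pipeline.yml --out results/ --seed 1
```

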