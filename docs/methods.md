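# Methods

This note records the models, the defaults and why they were chosen, what
the synthetic generator does and does not emulate, and the numerical and
design decisions a maintainer would want to know. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Growth model and detrending

Ring widths (mm) are converted to basal area increment assuming concentric
growth: radii accumulate from an optional pith offset (default 0 — per-tree
metadata, not estimated), and BAIₜ = π(r²ₜ − r²ₜ₋₁), which telescopes to the
total basal area exactly (tested to machine precision).

Regional Curve Standardization aligns raw BAI on 1-based cambial age,
averages across trees, truncates where fewer than `min_trees` (default 3)
contribute, and smooths with a centered moving average of width
max(5, 10 % of the oldest retained age). The smoother is deliberately a
moving average, not a spline: simple, deterministic, and testable (its only
claim is roughness reduction, which a unit test checks). Chronologies are
arithmetic means across trees per calendar year — the robust biweight mean
is deliberately omitted for determinism. Rings older than the curve's
coverage are dropped with a logged warning, never silently.

**Known limitation (signal absorption).** When cambial age correlates with
calendar year — any near-even-aged stand — the estimated regional curve
absorbs part of the common environmental signal, attenuating downstream
regression slopes on the water balance by roughly 10–20 % in the synthetic
stand. Detrending by the *true* ontogenetic curve removes the bias
entirely (both facts are asserted in the test suite). Real-world RCS has
the same property; treat absolute response magnitudes from RCS residuals
as conservative.

EPS uses the standard form n·r̄/(n·r̄ + 1 − r̄) over a common period with at
least 10 overlapping years; it applies to ring-width or BAI input (the
conventional choice, ring width, is the pipeline default).

Prewhitening estimates the lag-1 Yule-Walker coefficient and returns
z-scored AR(1) residuals (length n − 1). Both sides of every seasonal
correlation are prewhitened so first-order persistence does not inflate
significance; monthly correlation functions use the raw series, as is
conventional for response-function screening.

## Isotope physiology

The discrimination chain is the simple linear model:
Δ13C = (δatm − δring)/(1 + δring/1000), ci/ca = (Δ − a)/(b − a),
iWUE = ca·(1 − ci/ca)·k with a = 4.4 ‰ (stomatal diffusion), b = 27 ‰
(RuBisCO carboxylation), k = 0.625 = 1/1.6 (diffusivity ratio of water
vapor to CO2). No photorespiration or mesophyll-conductance terms. The
constants are configurable and recorded in the pipeline manifest.
ci/ca outside (0, 1) is flagged, never clamped. δ18O is carried through
untransformed and interpreted only statistically (no Craig–Gordon/Péclet
leaf-water model).

## Climatic water balance

PET uses the classical Hargreaves (1985) daily form
0.0023·Ra·(Tmean + 17.8)·√(Tmax − Tmin), floored at zero (the formula goes
negative below −17.8 °C), scaled by leap-aware month length.
Extraterrestrial radiation Ra follows FAO-56 at the mid-month day of year,
with the sunset-hour-angle argument clamped to [−1, 1] so polar night gives
Ra = 0. The summer moisture statistic is the *mean* of monthly W = P − PET
over June–August (a sum option exists); standardization is a z-score with
an optional reference period. Water-year deposition totals run previous
October through current September, labeled by the September year; annual
input is passed through unchanged. VPDmax is accepted as data only, never
derived from temperature.

## Climate response

Correlation functions cover previous-June through current-September by
default. The bootstrap resamples calendar years iid with replacement
(pairs jointly), n_boot = 1000, percentile CI at 1 − α; a cell is
significant when the CI excludes zero. No multiple-testing correction is
applied across the window by default (matching common response-function
practice); a Bonferroni option exists. Null calibration (per-cell
false-positive rate ≈ α) is asserted in the acceptance suite.

## Piecewise SEM

Each endogenous variable gets a linear mixed model with a tree-level
random intercept, estimated by REML implemented in `dendrosem.lmm`: the
variance ratio λ = σ²_u/σ²_e is profiled (per-group Sherman–Morrison
inverse), the restricted likelihood is minimized over a log-λ grid plus
bounded Brent refinement with the λ = 0 boundary admitted, and β follows
by GLS. On balanced one-way layouts this reproduces the closed-form ANOVA
estimator σ̂²_u = max(0, (MSB − MSW)/m) to 1e−6 (tested, alongside a
statsmodels MixedLM cross-check). Fixed-effect t tests use containment
style degrees of freedom n − rank(X) − (n_groups − 1); Satterthwaite
approximation was deliberately omitted for implementability, and the
difference matters little at the pipeline's sample sizes (CI coverage of a
planted slope is 93–97 % in simulation, asserted).

d-separation basis set: one claim per unordered non-adjacent pair,
excluding exogenous–exogenous pairs (their covariance is free) and
declared correlated-error pairs (the double-headed arrows, summarized
instead as residual correlations of the component models). The
topologically later node is the regression target (exogenous nodes first
in name order, then endogenous in lexicographic topological order — the
tie-break is deterministic); the conditioning set is the union of both
nodes' direct parents. Claim p-values are floored at 1e−12 and combined as
Fisher's C = −2Σln p ~ χ²(2k); AICc = C + 2K·n/(n − K − 1) with K = fixed
effects + 2 variance components summed over component models and n = rows.
Both marginal and conditional R² are always reported (var(Xβ̂) against
var(Xβ̂) + σ²_u + σ²_e). Raw, untransformed series enter the SEM so that
trends in the drivers remain part of the inference; the default analysis
window is 1981–2014, a config value.

The default path diagram has four exogenous drivers (summer water balance,
CO2, SO4, N) and three responses (Δ13C *or* iWUE, δ18O, residual BAI),
with free covariation among drivers and among response residuals. Note
that iWUE = 0.625·ca·(1 − ci/ca) contains ca by definition, so the
CO2→iWUE path in the iWUE variant is partly mechanical and can rival the
water path; the Δ13C variant is the cleaner attribution surface.

## Regime-shift statistics

Pettitt: Uₜ = Σᵢ≤ₜΣⱼ>ₜ sgn(xᵢ − xⱼ), sgn(0) = 0, earliest argmax on ties,
p = min(1, 2·exp(−6K²/(n³ + n²))). Mann-Kendall uses the tie-corrected
variance and ±1 continuity correction; Theil-Sen is the median pairwise
slope (scipy) with median-residual intercept; the two-sample KS p comes
from the asymptotic Kolmogorov series at effective size n_a·n_b/(n_a+n_b),
truncated when terms fall below 1e−10 (exact small-sample enumeration is a
non-goal). Series entering period comparisons are z-scored over their full
span first. The change-point year is defined as the *last* year of the
first regime.

**Known limitation (localization).** Pettitt reliably *detects* a 1-SD
mean shift in a century-scale series, but its *localization* error is
of order 1/δ² observations: in simulation the estimated year falls within
±2 years of the planted one only about half the time at δ = 1 SD. Treat
the detected year as a regime indicator, not a precise date.

## Synthetic generator

What it emulates: a temperate mesic broadleaf stand at 41.4° N, 15 trees
per species recruited over 1895–1915, 1895–2014 monthly climate; a wet
regime imposed as an additive increase in June–August precipitation after
1983 calibrated to `wet_shift` (default 1) standard deviations of the
pre-shift seasonal water-balance mean (precipitation component; PET noise
adds ~1–2 % to the realized SD, so the realized standardized shift is
slightly below nominal); CO2 as an exponential-plus-offset 290→400 ppm;
atmospheric δ13C declining linearly −6.5→−8.5 ‰; SO4 and N deposition as
piecewise-linear rise/decline (peaks 1972 and 1990) with lognormal noise.
The deposition noise SD is 0.15: water-year wet-deposition totals in
monitoring records vary by roughly 15–25 % year to year because they are
precipitation-weighted, and near-noise-free deposition curves would be
collinear with CO2 to a degree real records are not. Temperature is a
sinusoid plus 0.01 °C yr⁻¹ warming and Gaussian noise; precipitation is
mean-corrected lognormal around a monthly climatology.

Growth: BAI = g(age)·exp(β_w·W̃ + uᵢ + ε) with a Hugershoff-form
g(a) = c·a^p·e^(−qa) + d (defaults c = 150, p = 0.7, q = 0.02, d = 50 mm²,
peaking near age 35 at ~1000 mm² yr⁻¹, realistic for dominant broadleaf
trees), β_w = 0.3 per SD of the standardized JJA water balance W̃,
σ_tree = 0.15, σ_noise = 0.25. Ring widths are back-computed from
cumulative basal area, so the growth model is exact in BAI space, where
the analysis operates.

Isotopes are generated for a 5-tree subsample over 1950–2014 (emulating a
latewood cellulose campaign): ci/ca = 0.65 + 0.02·W̃ + 0.0001·ΔCO2 + tree
offset + noise, inverted exactly through the discrimination equations so
the forward pipeline recovers the planted ci/ca (exact at zero noise —
tested); δ18O = 28 − 0.5·W̃ + S(t) + tree offset + noise with a
−0.01 ‰ yr⁻¹ source-water decline S(t). The within- vs between-tree
variance split of the isotope channels is not constrained by any published
stand statistic; the defaults (tree SD 0.01 ci/ca-units and 0.25 ‰ δ18O
against residual SDs 0.025 and 0.35) are free parameters chosen to sit
near the measurement-precision floor of cellulose isotope work, and are
flagged as such.

All randomness fans out from one master seed into named substreams
(climate, environment, trees, isotopes), so regenerating any channel is
bit-for-bit reproducible and independent of the others.

What it does **not** emulate: spatial climate fields, crossdating error,
missing rings, species-specific leaf-level gas-exchange mechanisms beyond
the linear ci/ca structure, autocorrelated climate noise, or real PRISM /
deposition-network / ice-core series (shapes, not published values, are
the contract). Passing tests therefore demonstrate correctness of the
statistical machinery under a known truth, not that real forests behave
this way.

## Problem sizes in the test and acceptance runs

The simulation batteries are sized for a single CPU: 200 seeds for
change-point and bootstrap calibration, 100 seeds for SEM calibration
(5 trees × 34 years per dataset), 50 seeds for the full-study sign and
dominance checks, 500 random instances (n ≤ 60) for the brute-force oracle
battery. These sizes give Monte-Carlo standard errors comfortably inside
the asserted margins.
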