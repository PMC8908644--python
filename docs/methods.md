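# Methods

This note documents the models, estimators, and design choices behind
`migclass`, the defaults that matter, what the synthetic generator does and
does not emulate, and the package's known limitations.

## Telemetry screening and coordinates

Raw collar tables are screened to **one fix per calendar day** (the fix
nearest local noon; equidistant ties keep the earlier fix).  Screening is
idempotent and days without fixes stay gaps.  Animal-years are half-open
365-day windows `[anchor, anchor+365 d)` counted in days, so leap days
fold into the day index rather than shifting the anchor.  Two anchors are
analysed by default — **calving (1 June)** and **winter (1 January)** —
because different ecotypes show fidelity to calving grounds or to
wintering areas; both are configurable.  The default minimum is 180 fixes
per animal-year for displacement fitting and 30 fixes per season for
range estimation.

All planar math is in kilometres so NSD is natively km².  Geographic
input is projected with an azimuthal equidistant projection on a
spherical earth (R = 6371.0088 km) centred on the data centroid; the
centre is recorded so runs are reproducible.  Within a ~500 km study
window, pairwise planar distances agree with great-circle distances to
well under 1% (verified in the test suite against a haversine oracle).
Datum-grade accuracy is not attempted; collar GPS error dwarfs the
spherical approximation at this scale.

## Displacement model family

Five mean curves for planar NSD (km²) at day `t` since the origin fix:

* migrant: `δ/(1+exp((θ−t)/φ₁)) − δ/(1+exp((θ₂−t)/φ₂))`,
  `θ₂ = θ + 2φ₁ + ρ + 2φ₂`
* mixed migrant: second amplitude `δ₂ = f·δ` with `f ∈ (0,1)` fitted as a
  fraction, so the final asymptote `δ−δ₂` is positive by construction
* disperser: `δ/(1+exp((θ−t)/φ₁))`
* resident: `γ` (closed-form: the series mean)
* nomad: `β·t` (closed-form linear fit through the origin)

The altitudinal family (signed displacement in metres) keeps migrant,
resident, and disperser only, adds an intercept `γ`, and allows negative
amplitudes (downhill migrations).  Parameter bounds: `θ ∈ [0, 365]`,
`φ ∈ [1, 120]` days, `ρ ∈ [ρ_min, 365]` with **ρ_min = 30 days** — an
animal must hold its distant range at least a month to count as
migratory.

**Noise-floor intercept (planar, default on).**  With isotropic position
scatter of sd σ about the mean path, `E[NSD] = mean curve + 2σ²`
(≈ 4σ² when the origin is itself a noisy fix).  The classical zero-floor
family cannot absorb this constant, and the mixed-migrant return
amplitude soaks it up instead, mislabelling ordinary migrants as mixed
migrants whenever σ is non-negligible relative to the migration distance.
All planar fits therefore carry a non-negative intercept (reported in
`gamma`, counted in `k`), exactly mirroring the intercept the altitudinal
variants need for origin-elevation error.  `FitConstraints(noise_floor=False)`
restores the strict family.

**Fitting.**  Bounded trust-region least squares (`scipy.optimize.
least_squares`, analytic Jacobians) from a deterministic multi-start
grid: θ over evenly spaced fractions of the year (3 starts), amplitude
over the observed displacement extreme and half of it, ρ from 45 and 100
days, φ from 10 days.  The grid is seedless; fits are reproducible by
construction.  Noise-free simulations are recovered to machine precision
(delta/theta/phi/rho all < 10⁻⁶ relative error).  If no start converges
the model is excluded from selection with `aic = +inf`.

**Selection.**  AIC in the Gaussian least-squares form
`n·ln(RSS/n) + 2(k+1)` (k free parameters, +1 for the error variance;
AIC, not AICc).  Among converged models within a **parsimony band of 2
AIC units** of the minimum, the fewest-parameter model wins (ties by the
order resident < migrant < mixed migrant < disperser < nomad).  The band
is the conventional "equally supported" interval; without it, strict
argmin selection loses a large fraction of true residents to
higher-parameter curves, whose expected AIC gain from fitting noise
(χ²_Δk vs penalty 2Δk) exceeds the penalty often enough to matter.
`parsimony_margin=0` restores strict argmin.  Candidate subsets: all
five models, a no-nomad subset, and a binary migrant/resident subset.

**rNSD start selection.**  NSD can be re-referenced to an optimized
origin.  Scoring candidate origins by whole-year model AIC is biased:
NSD noise variance grows with NSD itself (Var ≈ 4σ²·NSD), so origins
displaced *toward* the migratory heading lower the plateau variance,
win the scan, and shrink the apparent migration distance (measured
d̂ ≈ 44–46 km for a true 50 km under σ = 5 km).  The default score is
therefore the **scan-window medoid**: the fix nearest the centroid of the
first 30 days after the anchor.  It is heading-unbiased, costs no model
fits, and cuts the mean absolute distance error from ~7% to ~3% under
the standard conditions.  The AIC scan remains available
(`score="aic"`).  The fitted θ is counted from the chosen origin fix.

Migration distance (one way) is `√δ̂` from a planar migrant or
mixed-migrant fit.

## Synthetic trajectory generator

Each behavioural class prescribes a deterministic mean path whose
**squared displacement follows the corresponding model curve exactly**;
the mean position sits at `√(curve(t))` along a fixed random heading.
(The simulator is deliberately coupled to the fitted family — the point
of the generator is well-posed parameter recovery and classification
ground truth, not behavioural realism.)  Nomads are a Brownian centre
walk with per-day variance 2D per axis, giving `E[NSD(t)] = 4Dt`.  Daily
position adds isotropic Gaussian noise (sd `home_sd_km`).  An optional
elevation layer follows the same logistic schedule between a low and a
high elevation (flat for residents and nomads) plus Gaussian noise.

Standard study conditions (the defaults of `BehaviourSpec` and
`experiments.STANDARD`): one-way distance 50 km, departure day 150,
transition 7 days, residency 60 days, mixed-migrant return offset 15 km,
diffusion 1 km²/day, position scatter 5 km, elevation band 800–1400 m
with 50 m noise.  The return offset is the one free constant the
conditions leave open; 15 km is far enough from both 0 and 50 km that
the mixed class is genuinely intermediate.

What the generator does **not** emulate: fix failures and irregular
sampling, collar error beyond iid Gaussian scatter, habitat- or
memory-driven movement, within-range autocorrelated movement (residency
is white noise about a centre), or correlated behaviour across years.
Passing tests therefore demonstrate correctness of the estimators under
the stated statistical model, not performance on any particular field
data set.

## Range overlap

Seasons: summer 1 July–15 September, winter 1 December–30 April
(inclusive; winter is labelled by the year it begins).  By default all
years are pooled per individual, giving one IO per animal; per-year
pairing is available.  UDs are fixed-kernel Gaussian estimates on a
regular grid with a single scalar reference bandwidth
`h = √((var_x+var_y)/2)·n^(−1/6)`; the grid extends 3h beyond the data
and mass is renormalized to 1.  The default cell is 1/50 of the joint
data extent; both seasons are rasterized on one shared grid so that
isopleth intersection is exact cell arithmetic.  The 95% isopleth is the
smallest set of cells (densest first, ties by cell index) holding 95% of
the mass; area is cell count × cell area.  `IO = 2A₁₂/(A₁+A₂)`;
`A₁₂ = 0` flags a clear migrant.  On a fine grid the Gaussian-UD 95%
isopleth area matches the analytic `π·5.991·σ²` ellipse to well under
5%, and translated uniform squares reproduce their overlap fraction to
±0.02.

Note that IO = 0 requires the far-range residency to span the winter
window: a migrant that returns home mid-winter contributes fixes from
both ranges to the winter sample and shows partial overlap.  This is a
property of the index, not an artefact.

## Plasticity and comparisons

`P = ΔC/(C_years − 1)` over the ordered yearly classifications; years
classified `unclassified` are dropped before computing P and remaining
years count as sequential.  Two schemes: **merged4** (mixed migrant
folded into migrant; resident, disperser, nomad kept) and **binary**
(requires classifications from the binary subset).  P is computed per
anchor.  Kruskal–Wallis (tie-corrected) compares IO between behaviours;
pairwise two-sided Mann–Whitney U tests run only when the omnibus
p < 0.05, without multiple-testing correction by default (the omnibus is
the gatekeeper; a Bonferroni flag is available).  Both statistics are
delegated to scipy and verified
against hand-computed rank formulas to 10⁻⁸.

## Problem sizes and runtime

The standard validation uses 50 animal-years per class (250 planar, 150
altitudinal), 20 series for the selection-oracle comparison, 1000
replicates for rank-test calibration, and 10,000 replicate years for the
nomad mean-squared-displacement check; the full validation completes in
about ten minutes on one CPU.  The analysis scripts use a 50-animal,
two-year population.

## Known limitations

* **Single-year nomadism is not identifiable from NSD shape.**  A single
  Brownian-walk year produces a smooth NSD realization that the flexible
  sigmoid curves fit far better (ΔAIC 20–400) than the one-parameter
  line, whose only advantage holds in expectation across realizations.
  Under the standard conditions ~90% of simulated nomads are labelled
  dispersers or mixed migrants, while the other four classes exceed 90%
  recovery.  Practitioners should treat the nomad label as reliable only
  in aggregate or over multiple years, and prefer the no-nomad subset
  when nomadism is implausible.
* Parameter estimates trade off within the transition window: under
  realistic noise, θ̂ and ρ̂ are recovered to within about a week, with
  2φ₁+ρ+2φ₂ (the round-trip span) much better determined than its parts.
* The overlap grid is deterministic but resolution-limited; halving the
  cell size changes IO by less than the documented ±0.02 square-test
  tolerance.
* Altitudinal classification ignores planar information entirely, as the
  method prescribes; animals migrating horizontally at constant elevation
  are altitudinal residents.
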