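# migclass

Seasonal-movement classification for GPS-collared animals: net-squared-
displacement (NSD) model selection, seasonal range overlap, and
inter-annual behavioural plasticity — with a built-in synthetic trajectory
generator so every stage can be validated against known ground truth.

## The problem

Northern ungulates (the motivating system is caribou) are partially
migratory: within one population some individuals migrate between distinct
seasonal ranges, others are resident, and some disperse permanently or
drift nomadically — and an individual may switch behaviour between years.
Given daily telemetry fixes, `migclass` answers three questions per
animal:

1. **Which seasonal-movement behaviour did it show each year?**
   The squared displacement from a start-of-year origin,
   NSD(t) = (x_t − x_0)² + (y_t − y_0)² (km²), is fit by a family of
   a-priori curves, one per behaviour:

   | behaviour      | mean NSD curve | shape |
   |----------------|----------------|-------|
   | migrant        | δ/(1+e^{(θ−t)/φ₁}) − δ/(1+e^{(θ₂−t)/φ₂}), θ₂ = θ+2φ₁+ρ+2φ₂ | bell |
   | mixed migrant  | δ/(1+e^{(θ−t)/φ₁}) − δ₂/(1+e^{(θ₂−t)/φ₂}), 0<δ₂<δ | bell, positive tail |
   | disperser      | δ/(1+e^{(θ−t)/φ₁}) | single sigmoid |
   | resident       | γ | flat |
   | nomad          | βt | line |

   δ is the squared one-way migration distance, θ the departure midpoint,
   φ₁/φ₂ transition timescales (days), and ρ the far-range residency,
   bounded below by 30 days so that a brief excursion does not count as
   migration.  The best model is chosen by AIC = n·ln(RSS/n) + 2(k+1);
   models within 2 AIC of the minimum resolve to the fewest-parameter one.
   An analogous three-model family (migrant/resident/disperser, signed
   amplitude plus intercept) classifies **altitudinal** migration from
   elevation displacement in metres.

2. **How separated are its summer and winter ranges?**
   Seasonal utilization distributions (fixed Gaussian kernel, reference
   bandwidth h = √((σ²ₓ+σ²ᵧ)/2)·n^(−1/6), ≥30 fixes per season) give 95%
   isopleth ranges with areas A₁ (summer, 1 Jul–15 Sep) and A₂ (winter,
   1 Dec–30 Apr).  The index of overlap is

       IO = 2·A₁₂ / (A₁ + A₂)  ∈ [0, 1],

   where A₁₂ is the intersection area; IO = 0 marks a "clear migrant".

3. **Does it switch behaviour between years?**
   For C_years classified years with ΔC switches between consecutive
   years, the plasticity metric is P = ΔC/(C_years − 1): 0 = fixed
   behaviour, 1 = switching every year.  IO is compared across behaviours
   with a Kruskal–Wallis omnibus test, followed by pairwise Mann–Whitney U
   tests when significant.

## Worked example

```python
import migclass as mc

spec = mc.BehaviourSpec("migrant", one_way_distance_km=50.0, departure_day=150.0,
                        transition_days=7.0, residency_days=60.0, home_sd_km=5.0)
traj, truth = mc.simulate_year(spec, seed=42, animal_id="cow_01")

sel = mc.select_start(traj, [(6, 1)], rnsd=True)[0]      # rNSD origin choice
year = mc.AnimalYear("cow_01", 2000, sel.start_date, traj.fixes)
series = mc.compute_nsd(year, sel.origin)
result = mc.classify(series, subset="all")

print("best model:", result.best_model)
print("delta AIC :", {m: round(d, 1) for m, d in sorted(result.delta_aic.items())})
fit = result.fits[result.best_model]
print(f"one-way distance: {mc.migration_distance(fit):.1f} km")
```

prints

```
best model: migrant
delta AIC : {'disperser': 879.8, 'migrant': 0.0, 'mixed_migrant': 2.0, 'nomad': 953.9, 'resident': 952.0}
one-way distance: 51.6 km
```

The simulated animal (a 50 km migrant with 5 km daily position scatter) is
recovered as a migrant with overwhelming AIC support over the
non-migratory shapes, and its one-way migration distance √δ̂ is estimated
within ~3%.  The fitted departure day is counted from the chosen origin
fix (here day 18 of the scan window), so θ̂ ≈ 132 corresponds to the true
departure at day 150 from the anchor.

## Analysis pipeline

The `analysis/` scripts run the full study on a labelled synthetic
population and write tables under `results/`:

```bash
python analysis/01_simulate_population.py   # 50 animals x 2 years, 5 behaviours
python analysis/02_classify_displacement.py # NSD classification vs truth
python analysis/03_seasonal_overlap.py      # per-animal IO + rank tests
python analysis/04_plasticity.py            # P for switching vs faithful animals
python analysis/05_summary_report.py        # end-to-end per-group summary table
```

The same pipeline is scriptable from a YAML config
(`migclass run --config cfg.yaml`, see `migclass --help` for `simulate`
and `report`), and each stage is importable from the library
(`migclass.telemetry`, `.simulate`, `.models`, `.overlap`, `.plasticity`,
`.pipeline`).

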