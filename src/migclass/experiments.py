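"""Standard validation experiments on the synthetic study conditions.

These drivers define the package's reference simulation conditions — one
year of daily fixes per animal, migration distance 50 km, departure around
day 150, week-scale transitions, two-month far-range residency, positional
scatter 5 km, nomadic diffusion 1 km²/day, and a 600 m elevational
amplitude with 50 m noise for the altitudinal variant — and measure how
well the classifier, the parameter estimates, the overlap index, the
plasticity metric, and the rank tests behave under them.  Both the test
suite and the acceptance script run these.
"""

from __future__ import annotations

import itertools
import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import models, overlap as ov, simulate as sim
from .telemetry import AnimalYear, Fix

PLANAR_CATEGORIES = ("migrant", "mixed_migrant", "resident", "disperser", "nomad")
ALTITUDINAL_CATEGORIES = ("migrant", "resident", "disperser")

STANDARD = dict(one_way_distance_km=50.0, departure_day=150.0,
                transition_days=7.0, residency_days=60.0,
                return_offset_km=15.0, diffusion_km2_per_day=1.0)


def _animal_year(traj) -> AnimalYear:
    return AnimalYear(traj.animal_id, traj.fixes[0].timestamp.year,
                      traj.fixes[0].timestamp.date(), traj.fixes)


def classification_experiment(seed: int, n_per_class: int = 50,
                              sigma_km: float = 5.0,
                              categories: Sequence[str] = PLANAR_CATEGORIES,
                              subset: str = "all", rnsd: bool = True,
                              constraints: Optional[models.FitConstraints] = None,
                              ) -> pd.DataFrame:
    """Simulate ``n_per_class`` animal-years per category and classify each.

    Returns one row per animal-year with the true category, the assigned
    category, and (when the best fit is migratory) the recovered one-way
    migration distance.
    """
    groups = [sim.PopulationGroup(
        sim.BehaviourSpec(c, home_sd_km=sigma_km, **STANDARD), n=n_per_class)
        for c in categories]
    trajs, truth = sim.simulate_population(groups, seed)
    rows = []
    for traj, (_, tr) in zip(trajs, truth.iterrows()):
        if rnsd:
            sel = models.select_start(traj, [(6, 1)], rnsd=True)
            origin = sel[0].origin if sel else traj.fixes[0]
        else:
            origin = traj.fixes[0]
        series = models.compute_nsd(_animal_year(traj), origin)
        res = models.classify(series, subset, constraints)
        dist = math.nan
        if res.best_model in ("migrant", "mixed_migrant"):
            dist = models.migration_distance(res.fits[res.best_model])
        rows.append({"animal_id": traj.animal_id, "true": tr.category,
                     "assigned": res.best_model,
                     "migration_distance_km": dist})
    return pd.DataFrame(rows)


def altitudinal_experiment(seed: int, n_per_class: int = 50,
                           amplitude_m: float = 600.0,
                           noise_m: float = 50.0) -> pd.DataFrame:
    """Elevational-displacement classification over the 3-model family."""
    groups = [sim.PopulationGroup(
        sim.BehaviourSpec(c, home_sd_km=5.0, elevation_low_m=800.0,
                          elevation_high_m=800.0 + amplitude_m,
                          elevation_sd_m=noise_m, **STANDARD),
        n=n_per_class) for c in ALTITUDINAL_CATEGORIES]
    trajs, truth = sim.simulate_population(groups, seed)
    rows = []
    for traj, (_, tr) in zip(trajs, truth.iterrows()):
        series = models.compute_elevation_displacement(_animal_year(traj))
        res = models.classify(series, "all")
        rows.append({"animal_id": traj.animal_id, "true": tr.category,
                     "assigned": res.best_model})
    return pd.DataFrame(rows)


def accuracy(table: pd.DataFrame) -> float:
    return float((table.true == table.assigned).mean())


def noise_free_recovery() -> dict[str, float]:
    """Worst relative parameter error of fits on noise-free simulations."""
    out = {}
    for cat in ("migrant", "mixed_migrant", "disperser"):
        spec = sim.BehaviourSpec(cat, home_sd_km=0.0, **STANDARD)
        traj, _ = sim.simulate_year(spec, 17, animal_id=cat)
        origin = Fix(cat, traj.fixes[0].timestamp, x=0.0, y=0.0)
        series = models.compute_nsd(_animal_year(traj), origin)
        fit = models.fit_model(series, cat)
        p = fit.params
        d2 = spec.one_way_distance_km ** 2
        errs = [abs(p.delta - d2) / d2,
                abs(p.theta - spec.departure_day) / spec.departure_day,
                abs(p.phi1 - spec.transition_days) / spec.transition_days]
        if cat != "disperser":
            errs += [abs(p.phi2 - spec.transition_days) / spec.transition_days,
                     abs(p.rho - spec.residency_days) / spec.residency_days]
        if cat == "mixed_migrant":
            d22 = d2 - spec.return_offset_km ** 2
            errs.append(abs(p.delta2 - d22) / d22)
        out[cat] = max(errs)
    return out


def random_series_pool(seed: int, n_series: int = 20):
    """Mixed-category noisy series for selection-oracle comparisons."""
    rng = np.random.default_rng(seed)
    cats = list(PLANAR_CATEGORIES)
    series = []
    for i in range(n_series):
        cat = cats[i % len(cats)]
        sigma = float(rng.uniform(2.0, 8.0))
        spec = sim.BehaviourSpec(cat, home_sd_km=sigma, **STANDARD)
        traj, _ = sim.simulate_year(spec, rng, animal_id=f"pool_{i:02d}")
        series.append(models.compute_nsd(_animal_year(traj)))
    return series


DENSE_ORACLE_GRID = models.FitConstraints(n_theta_starts=8,
                                          extra_delta_starts=3,
                                          rho_starts=(35.0, 60.0, 90.0, 150.0))


def aic_oracle_agreement(seed: int, n_series: int = 20,
                         subset: str = "all") -> float:
    """Fraction of series where default classification equals a brute-force
    re-selection that refits every candidate from a dense start grid."""
    agree = 0
    for series in random_series_pool(seed, n_series):
        res = models.classify(series, subset)
        oracle_fits = {m: models.fit_model(series, m, DENSE_ORACLE_GRID)
                       for m in models.candidate_models(series.mode, subset)}
        oracle_best = models.select_best(oracle_fits,
                                         DENSE_ORACLE_GRID.parsimony_margin)
        agree += res.best_model == oracle_best
    return agree / n_series


# ---------------------------------------------------------------------------
# overlap / plasticity / rank-test checks
# ---------------------------------------------------------------------------

def square_overlap_errors(fractions=(0.0, 0.25, 0.5, 0.75, 1.0),
                          cell: float = 0.02) -> dict[float, float]:
    """|IO - f| for unit squares constructed to overlap by fraction f."""
    out = {}
    for f in fractions:
        shift = 1.0 - f
        xs = np.arange(cell / 2, 4.0, cell)
        X, Y = np.meshgrid(xs, xs)

        def square_range(x0):
            inside = ((X >= x0) & (X < x0 + 1.0) & (Y >= 1.0) & (Y < 2.0))
            dens = inside / (inside.sum() * cell * cell)
            ud = ov.UD(xs, xs, dens, cell, 1.0)
            mask, area = ov.isopleth(ud, 0.95)
            return ov.SeasonalRange("sq", "s", 99, ud, mask, area)

        res = ov.index_overlap(square_range(1.0), square_range(1.0 + shift))
        out[f] = abs(res.io - f)
    return out


def gaussian_isopleth_area_error(cell: float = 0.05) -> float:
    """Relative error of the 95% isopleth area of an isotropic Gaussian UD
    against the analytic ellipse area pi * chi2_2(0.95) * sigma^2."""
    xs = np.arange(-5 + cell / 2, 5, cell)
    X, Y = np.meshgrid(xs, xs)
    dens = np.exp(-(X ** 2 + Y ** 2) / 2) / (2 * math.pi)
    dens /= dens.sum() * cell * cell
    _, area = ov.isopleth(ov.UD(xs, xs, dens, cell, 1.0), 0.95)
    expect = math.pi * 5.991
    return abs(area - expect) / expect


def plasticity_enumeration_max_error(max_len: int = 5) -> float:
    """Worst |P - switches/(L-1)| over every category sequence up to
    ``max_len`` years (brute-force enumeration)."""
    from .plasticity import plasticity
    cats = ("migrant", "resident", "disperser", "nomad")
    worst = 0.0
    for length in range(2, max_len + 1):
        for seq in itertools.product(cats, repeat=length):
            switches = sum(a != b for a, b in zip(seq, seq[1:]))
            worst = max(worst, abs(plasticity(list(seq)).p
                                   - switches / (length - 1)))
    return worst


def kruskal_type1_rate(seed: int, n_rep: int = 1000, n_groups: int = 3,
                       n_per_group: int = 15, alpha: float = 0.05) -> float:
    """Omnibus rejection rate when all groups share one distribution."""
    rng = np.random.default_rng(seed)
    from .plasticity import compare_overlap_by_category
    rejections = 0
    for _ in range(n_rep):
        groups = {f"g{i}": rng.normal(0.0, 1.0, n_per_group).tolist()
                  for i in range(n_groups)}
        res = compare_overlap_by_category(groups, alpha=alpha)
        rejections += res.p_value < alpha
    return rejections / n_rep


def nomad_msd_slope_ratio(seed: int, n_rep: int = 10_000,
                          diffusion: float = 1.0,
                          probe_days=(50, 150, 300)) -> float:
    """Monte-Carlo mean squared displacement of the nomad simulator at the
    probe days, fitted against the Brownian expectation 4*D*t; returns the
    fitted/expected slope ratio."""
    root = np.random.SeedSequence(seed)
    probes = np.asarray(probe_days)
    acc = np.zeros(len(probes))
    spec = sim.BehaviourSpec("nomad", diffusion_km2_per_day=diffusion,
                             home_sd_km=0.0)
    for ss in root.spawn(n_rep):
        traj, _ = sim.simulate_year(spec, np.random.default_rng(ss))
        xy = traj.xy()
        acc += (xy[probes] ** 2).sum(axis=1)
    msd = acc / n_rep
    t = probes.astype(float)
    slope = float((t * msd).sum() / (t * t).sum())
    return slope / (4.0 * diffusion)


def simulator_consistency_max_relerr() -> float:
    """Worst relative deviation between noise-free simulated NSD and the
    corresponding model mean curve, across the deterministic classes."""
    worst = 0.0
    for cat in ("migrant", "mixed_migrant", "resident", "disperser"):
        spec = sim.BehaviourSpec(cat, home_sd_km=0.0, **STANDARD)
        traj, _ = sim.simulate_year(spec, 13, animal_id=cat)
        origin = Fix(cat, traj.fixes[0].timestamp, x=0.0, y=0.0)
        series = models.compute_nsd(_animal_year(traj), origin)
        expected = sim.mean_squared_displacement(spec, series.t)
        scale = max(float(np.max(expected)), 1.0)
        worst = max(worst, float(np.abs(series.value - expected).max()) / scale)
    return worst
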