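"""Synthetic daily GPS trajectories with known behavioural ground truth.

Each behavioural class prescribes a mean path whose squared displacement
follows the corresponding displacement-model curve exactly, so simulator
and classifier are mutually consistent by construction:

* migrant        — out to a range ``d`` km away, residency ``rho`` days,
                   return to the origin (double-logistic squared
                   displacement along a fixed heading);
* mixed_migrant  — as migrant but settling ``r`` km from the origin;
* disperser      — one-way logistic shift of ``d`` km;
* resident       — fixed centre;
* nomad          — Brownian centre walk with per-day variance ``2D`` per
                   axis, giving E[NSD(t)] = 4Dt.

Daily position = mean path + isotropic Gaussian noise (sd ``home_sd_km``).
An optional elevation layer follows the same logistic schedule between a
low and a high elevation, supporting altitudinal-displacement analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .models import ModelParams, model_predict
from .telemetry import Fix, Trajectory

CATEGORIES = ("migrant", "mixed_migrant", "resident", "disperser", "nomad")


class SpecificationError(ValueError):
    """A behaviour spec violates one of its invariants."""


@dataclass
class BehaviourSpec:
    """Ground-truth parameters for one behavioural class.

    Distances in km, times in days, elevations in m.  ``departure_day``,
    ``transition_days`` and ``residency_days`` are the true counterparts of
    the fitted theta/phi/rho; ``one_way_distance_km`` corresponds to
    sqrt(delta).
    """

    category: str
    one_way_distance_km: float = 50.0
    departure_day: float = 150.0
    transition_days: float = 7.0
    residency_days: float = 60.0
    return_offset_km: float = 15.0  # mixed migrant only: final centre offset
    diffusion_km2_per_day: float = 1.0  # nomad only
    home_sd_km: float = 5.0
    elevation_low_m: Optional[float] = None
    elevation_high_m: Optional[float] = None
    elevation_sd_m: float = 50.0

    def validate(self) -> None:
        if self.category not in CATEGORIES:
            raise SpecificationError(f"unknown category {self.category!r}")
        if self.home_sd_km < 0:
            raise SpecificationError("home_sd_km must be >= 0")
        if self.category in ("migrant", "mixed_migrant", "disperser"):
            if self.one_way_distance_km <= 0:
                raise SpecificationError("one_way_distance_km must be > 0")
        if self.category in ("migrant", "mixed_migrant"):
            end = (self.departure_day + 2 * self.transition_days
                   + self.residency_days)
            if not 0 < self.departure_day < end < 365:
                raise SpecificationError(
                    "need 0 < departure_day < departure_day + 2*transition_days"
                    " + residency_days < 365")
        if self.category == "mixed_migrant":
            if not 0 < self.return_offset_km < self.one_way_distance_km:
                raise SpecificationError(
                    "need 0 < return_offset_km < one_way_distance_km")
        if self.category == "nomad" and self.diffusion_km2_per_day < 0:
            raise SpecificationError("diffusion_km2_per_day must be >= 0")

    @property
    def has_elevation(self) -> bool:
        return self.elevation_low_m is not None and self.elevation_high_m is not None

    def model_params(self) -> Optional[ModelParams]:
        """The displacement-model parameters the noise-free mean NSD obeys
        (None for nomad, whose mean NSD 4Dt holds only in expectation)."""
        d2 = self.one_way_distance_km ** 2
        if self.category == "migrant":
            return ModelParams(delta=d2, theta=self.departure_day,
                               phi1=self.transition_days, phi2=self.transition_days,
                               rho=self.residency_days)
        if self.category == "mixed_migrant":
            return ModelParams(delta=d2, theta=self.departure_day,
                               phi1=self.transition_days, phi2=self.transition_days,
                               rho=self.residency_days,
                               delta2=d2 - self.return_offset_km ** 2)
        if self.category == "disperser":
            return ModelParams(delta=d2, theta=self.departure_day,
                               phi1=self.transition_days)
        if self.category == "resident":
            return ModelParams(gamma=0.0)
        return None


def mean_squared_displacement(spec: BehaviourSpec, t: np.ndarray) -> np.ndarray:
    """Noise-free mean NSD curve (km²) for the deterministic classes."""
    if spec.category == "nomad":
        return 4.0 * spec.diffusion_km2_per_day * np.asarray(t, dtype=float)
    name = spec.category
    return model_predict(name, spec.model_params(), t, mode="planar")


def _elevation_schedule(spec: BehaviourSpec, t: np.ndarray) -> np.ndarray:
    """Mean elevation: logistic seasonal profile between low and high."""
    lo, hi = spec.elevation_low_m, spec.elevation_high_m
    th, ph = spec.departure_day, spec.transition_days
    if spec.category in ("migrant", "mixed_migrant"):
        th2 = th + 2 * ph + spec.residency_days + 2 * ph
        frac = (1.0 / (1.0 + np.exp((th - t) / ph))
                - 1.0 / (1.0 + np.exp((th2 - t) / ph)))
    elif spec.category == "disperser":
        frac = 1.0 / (1.0 + np.exp((th - t) / ph))
    else:  # resident, nomad: no seasonal elevation shift
        frac = np.zeros_like(t)
    return lo + (hi - lo) * frac


def simulate_year(spec: BehaviourSpec, seed, animal_id: str = "sim",
                  year_label: int = 2000,
                  start_date: Optional[date] = None) -> tuple[Trajectory, dict]:
    """One 365-day animal-year of daily fixes plus its truth-table row.

    ``seed`` may be an int or a numpy SeedSequence/Generator; output is
    fully reproducible from it.
    """
    spec.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if start_date is None:
        start_date = date(year_label, 6, 1)
    t = np.arange(365, dtype=float)

    if spec.category == "nomad":
        steps = rng.normal(0.0, math.sqrt(2.0 * spec.diffusion_km2_per_day), size=(365, 2))
        steps[0] = 0.0
        mean_xy = np.cumsum(steps, axis=0)
    else:
        s = np.sqrt(mean_squared_displacement(spec, t))
        heading = rng.uniform(0.0, 2.0 * math.pi)
        u = np.array([math.cos(heading), math.sin(heading)])
        mean_xy = s[:, None] * u[None, :]

    xy = mean_xy + rng.normal(0.0, spec.home_sd_km, size=(365, 2)) if spec.home_sd_km > 0 else mean_xy

    if spec.has_elevation:
        elev = _elevation_schedule(spec, t)
        if spec.elevation_sd_m > 0:
            elev = elev + rng.normal(0.0, spec.elevation_sd_m, size=365)
    else:
        elev = np.full(365, math.nan)

    fixes = [
        Fix(animal_id,
            datetime.combine(start_date + timedelta(days=int(i)), time(12, 0)),
            x=float(xy[i, 0]), y=float(xy[i, 1]), elevation=float(elev[i]))
        for i in range(365)
    ]
    truth = {
        "animal_id": animal_id,
        "year_label": year_label,
        "category": spec.category,
        "one_way_distance_km": spec.one_way_distance_km,
        "departure_day": spec.departure_day,
        "transition_days": spec.transition_days,
        "residency_days": spec.residency_days,
        "return_offset_km": spec.return_offset_km if spec.category == "mixed_migrant" else math.nan,
        "diffusion_km2_per_day": spec.diffusion_km2_per_day if spec.category == "nomad" else math.nan,
        "home_sd_km": spec.home_sd_km,
        "has_elevation": spec.has_elevation,
    }
    return Trajectory(animal_id, fixes), truth


@dataclass
class PopulationGroup:
    """``n`` animals following ``spec`` for ``n_years`` years; an optional
    per-year ``schedule`` of categories overrides ``spec.category`` year by
    year (enabling plasticity experiments)."""

    spec: BehaviourSpec
    n: int = 1
    n_years: int = 1
    schedule: Optional[Sequence[str]] = None
    label: Optional[str] = None


def simulate_population(groups: Sequence[PopulationGroup], seed: int,
                        first_year: int = 2000,
                        anchor: tuple[int, int] = (6, 1)) -> tuple[list[Trajectory], pd.DataFrame]:
    """Simulate a labelled population; deterministic given ``seed``.

    Multi-year animals concatenate independent year simulations about a
    common origin.  Returns the trajectories and the complete truth table
    (one row per simulated animal-year).
    """
    if not groups:
        raise ValueError("empty population config")
    root = np.random.SeedSequence(seed)
    trajectories: list[Trajectory] = []
    rows: list[dict] = []
    g_seeds = root.spawn(len(groups))
    for gi, grp in enumerate(groups):
        label = grp.label or grp.spec.category
        n_years = len(grp.schedule) if grp.schedule else grp.n_years
        a_seeds = g_seeds[gi].spawn(grp.n)
        for ai in range(grp.n):
            animal_id = f"{label}_{ai:03d}"
            rng = np.random.default_rng(a_seeds[ai])
            fixes: list[Fix] = []
            for yi in range(n_years):
                yspec = grp.spec
                if grp.schedule:
                    from dataclasses import replace as _replace
                    yspec = _replace(grp.spec, category=grp.schedule[yi])
                year = first_year + yi
                start = date(year, anchor[0], anchor[1])
                traj, truth = simulate_year(yspec, rng, animal_id, year, start)
                fixes.extend(traj.fixes)
                truth["group"] = label
                rows.append(truth)
            trajectories.append(Trajectory(animal_id, fixes))
    return trajectories, pd.DataFrame(rows)


def trajectories_to_frame(trajectories: Sequence[Trajectory]) -> pd.DataFrame:
    """Normalized interchange table: animal_id, date, x_km, y_km, elev_m."""
    return pd.concat([t.to_frame() for t in trajectories], ignore_index=True)
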