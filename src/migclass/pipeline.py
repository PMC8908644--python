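"""End-to-end orchestration: config in, per-animal tables and a summary out.

A run takes either a telemetry file or a synthetic-population spec,
screens trajectories to daily fixes, classifies every animal-year by NSD
(and altitudinal displacement where elevation exists) for each requested
(anchor, subset) combination, computes per-animal seasonal-range overlap,
derives plasticity, and emits a summary table in the style of a
per-group report: % of animal-years per category, median/mean IO, % clear
migrants, and migration distances.  Every skipped animal-year is logged
with a reason, and the run is deterministic given config and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import models, overlap as ov, simulate as sim, telemetry as tel
from .plasticity import SequenceTooShortError, merge_categories, plasticity as _plasticity

DEFAULT_ANCHORS = {"calving": (6, 1), "winter": (1, 1)}


@dataclass
class RunConfig:
    """Everything a run needs; every default is printed into the run log."""

    out_dir: str = "results/run"
    seed: int = 0
    input_path: Optional[str] = None
    schema: dict = field(default_factory=dict)
    projection_centre: Optional[tuple[float, float]] = None
    simulate_groups: list = field(default_factory=list)  # list[sim.PopulationGroup]
    anchors: dict = field(default_factory=lambda: dict(DEFAULT_ANCHORS))
    subsets: tuple = ("all", "no_nomad", "binary")
    modes: tuple = ("planar",)
    rho_min: float = 30.0
    rnsd: bool = True
    rnsd_scan_days: int = 30
    min_fixes_year: int = 180
    min_fixes_season: int = 30
    summer: ov.SeasonWindow = ov.SUMMER
    winter: ov.SeasonWindow = ov.WINTER
    group_labels: dict = field(default_factory=dict)  # animal_id -> group

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        simple = {"out_dir", "seed", "input_path", "schema", "rho_min", "rnsd",
                  "rnsd_scan_days", "min_fixes_year", "min_fixes_season",
                  "group_labels"}
        for key, val in raw.items():
            if key in simple:
                setattr(cfg, key, val)
            elif key == "projection_centre":
                cfg.projection_centre = tuple(val)
            elif key == "anchors":
                cfg.anchors = {k: tuple(v) for k, v in val.items()}
            elif key in ("subsets", "modes"):
                setattr(cfg, key, tuple(val))
            elif key == "seasons":
                if "summer" in val:
                    s = val["summer"]
                    cfg.summer = ov.SeasonWindow("summer", tuple(s[0]), tuple(s[1]))
                if "winter" in val:
                    w = val["winter"]
                    cfg.winter = ov.SeasonWindow("winter", tuple(w[0]), tuple(w[1]))
            elif key == "simulate":
                for g in val.get("groups", []):
                    spec_kwargs = {k: v for k, v in g.items()
                                   if k not in ("n", "n_years", "schedule", "label")}
                    cfg.simulate_groups.append(sim.PopulationGroup(
                        sim.BehaviourSpec(**spec_kwargs),
                        n=g.get("n", 1), n_years=g.get("n_years", 1),
                        schedule=g.get("schedule"), label=g.get("label")))
            else:
                raise KeyError(f"unknown config key {key!r}")
        return cfg


@dataclass
class RunResult:
    classification: pd.DataFrame
    overlap: pd.DataFrame
    plasticity: pd.DataFrame
    summary: pd.DataFrame
    truth: Optional[pd.DataFrame]
    log_lines: list[str]


def _load_trajectories(cfg: RunConfig, log: list[str]):
    truth = None
    if cfg.simulate_groups:
        trajs, truth = sim.simulate_population(cfg.simulate_groups, cfg.seed)
        log.append(f"simulated {len(trajs)} animals, {len(truth)} animal-years")
        groups = dict(zip(truth.animal_id, truth.group))
    elif cfg.input_path:
        rej = tel.RejectLog()
        by_animal = tel.read_telemetry(cfg.input_path, cfg.schema or None, log=rej)
        trajs = []
        for aid, fixes in sorted(by_animal.items()):
            if fixes and not math.isfinite(fixes[0].x):
                fixes, centre = tel.project_to_planar(fixes, cfg.projection_centre, rej)
                log.append(f"{aid}: projected about centre {centre}")
            trajs.append(tel.screen_to_daily(fixes, aid))
        log.append(f"read {len(trajs)} animals; {rej.n} rows rejected")
        for item, reason in rej.records:
            log.append(f"  reject {item}: {reason}")
        groups = dict(cfg.group_labels)
    else:
        raise ValueError("config must give input_path or simulate.groups")
    return trajs, truth, groups


def _classify_all(cfg: RunConfig, trajs, log: list[str]) -> pd.DataFrame:
    cons = models.FitConstraints(rho_min=cfg.rho_min)
    rows = []
    rej = tel.RejectLog()
    for traj in trajs:
        for anchor_name, anchor in cfg.anchors.items():
            ays = tel.split_animal_years(traj, anchor, cfg.min_fixes_year, rej)
            for ay in ays:
                sels = models.select_start(
                    tel.Trajectory(traj.animal_id, ay.fixes), [anchor],
                    rnsd=cfg.rnsd, scan_days=cfg.rnsd_scan_days,
                    constraints=cons, log=rej)
                if not sels:
                    continue
                origin = sels[0].origin
                for mode in cfg.modes:
                    try:
                        if mode == "planar":
                            series = models.compute_nsd(ay, origin, anchor_name)
                        else:
                            series = models.compute_elevation_displacement(
                                ay, start_anchor=anchor_name)
                    except ValueError as e:
                        rej.add(f"{ay.animal_id}/{ay.year_label}", str(e))
                        continue
                    subsets = cfg.subsets if mode == "planar" else tuple(
                        s for s in cfg.subsets if s in ("all", "binary"))
                    for subset in subsets:
                        res = models.classify(series, subset, cons)
                        best = res.fits.get(res.best_model)
                        dist = math.nan
                        if best and best.model_name in ("migrant", "mixed_migrant") \
                                and mode == "planar":
                            dist = models.migration_distance(best)
                        rows.append({
                            "animal_id": ay.animal_id, "year_label": ay.year_label,
                            "mode": mode, "anchor": anchor_name, "subset": subset,
                            "best_model": res.best_model,
                            "migration_distance_km": dist,
                            **{f"aic_{m}": f.aic for m, f in res.fits.items()},
                            **({f"par_{k}": v for k, v in best.params.as_dict().items()}
                               if best else {}),
                        })
    for item, reason in rej.records:
        log.append(f"  skip {item}: {reason}")
    log.append(f"classified {len(rows)} (animal-year x mode x anchor x subset) rows; "
               f"{rej.n} skips")
    return pd.DataFrame(rows)


def _overlap_all(cfg: RunConfig, trajs, log: list[str]) -> pd.DataFrame:
    rej = tel.RejectLog()
    rows = []
    for traj in trajs:
        res = ov.overlap_for_animal(traj, cfg.summer, cfg.winter,
                                    min_fixes=cfg.min_fixes_season, log=rej)
        if res is None:
            continue
        rows.append({"animal_id": res.animal_id, "A1_km2": res.A1,
                     "A2_km2": res.A2, "A12_km2": res.A12, "io": res.io,
                     "clear_migrant": res.clear_migrant})
    for item, reason in rej.records:
        log.append(f"  overlap skip {item}: {reason}")
    log.append(f"overlap computed for {len(rows)} animals; {rej.n} excluded")
    return pd.DataFrame(rows)


def _plasticity_all(cfg: RunConfig, classification: pd.DataFrame,
                    log: list[str]) -> pd.DataFrame:
    rows = []
    if classification.empty:
        return pd.DataFrame(rows)
    for (aid, mode, anchor, subset), grp in classification.groupby(
            ["animal_id", "mode", "anchor", "subset"]):
        grp = grp.sort_values("year_label")
        cats = [c for c in grp.best_model if c != "unclassified"]
        scheme = "binary" if subset == "binary" else "merged4"
        if subset == "no_nomad":
            continue  # P is reported for the all(merged4) and binary schemes
        try:
            merged = merge_categories(cats, scheme)
            rec = _plasticity(merged, aid, scheme)
        except (SequenceTooShortError, ValueError) as e:
            log.append(f"  plasticity skip {aid}/{mode}/{anchor}/{scheme}: {e}")
            continue
        rows.append({"animal_id": aid, "mode": mode, "anchor": anchor,
                     "scheme": scheme, "n_years": len(merged),
                     "n_switches": rec.n_switches, "p": rec.p})
    log.append(f"plasticity computed for {len(rows)} animal x scheme records")
    return pd.DataFrame(rows)


def _summarize(cfg: RunConfig, classification: pd.DataFrame,
               overlap: pd.DataFrame, groups: dict) -> pd.DataFrame:
    """Per-group report rows: category %, IO stats, clear-migrant %, and
    one-way migration distances.  Percentages within one (mode, anchor,
    subset) sum to 100 over classified animal-years."""
    rows = []
    if classification.empty:
        return pd.DataFrame(rows)
    cls = classification.copy()
    cls["group"] = cls.animal_id.map(lambda a: groups.get(a, "all"))
    if not overlap.empty:
        overlap = overlap.copy()
        overlap["group"] = overlap.animal_id.map(lambda a: groups.get(a, "all"))
    for (group, mode, anchor, subset), grp in cls.groupby(
            ["group", "mode", "anchor", "subset"]):
        classified = grp[grp.best_model != "unclassified"]
        n = len(classified)
        pct = (classified.best_model.value_counts() / max(n, 1) * 100.0)
        migr = classified[classified.best_model.isin(["migrant", "mixed_migrant"])]
        row = {"group": group, "mode": mode, "anchor": anchor, "subset": subset,
               "n_animal_years": n}
        for cat in models.PLANAR_MODELS:
            row[f"pct_{cat}"] = float(pct.get(cat, 0.0))
        dist = migr.migration_distance_km.dropna()
        row["median_migration_km"] = float(dist.median()) if len(dist) else math.nan
        row["mean_migration_km"] = float(dist.mean()) if len(dist) else math.nan
        if not overlap.empty:
            og = overlap[overlap.group == group]
            row["median_io"] = float(og.io.median()) if len(og) else math.nan
            row["mean_io"] = float(og.io.mean()) if len(og) else math.nan
            row["pct_clear_migrants"] = (float(og.clear_migrant.mean() * 100.0)
                                         if len(og) else math.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def run(cfg: RunConfig, write: bool = True) -> RunResult:
    """Execute the full analysis; optionally write all tables and the log."""
    log: list[str] = [f"config: {cfg}"]
    trajs, truth, groups = _load_trajectories(cfg, log)
    if truth is not None:
        truth_groups = {a: g for a, g in zip(truth.animal_id, truth.group)}
        groups = {**truth_groups, **groups}
    classification = _classify_all(cfg, trajs, log)
    overlap = _overlap_all(cfg, trajs, log)
    plasticity = _plasticity_all(cfg, classification, log)
    summary = _summarize(cfg, classification, overlap, groups)
    result = RunResult(classification, overlap, plasticity, summary, truth, log)
    if write:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        classification.to_csv(out / "classification.csv", index=False)
        overlap.to_csv(out / "overlap.csv", index=False)
        plasticity.to_csv(out / "plasticity.csv", index=False)
        summary.to_csv(out / "summary.csv", index=False)
        if truth is not None:
            truth.to_csv(out / "truth.csv", index=False)
        (out / "run_log.txt").write_text("\n".join(log) + "\n")
    return result
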