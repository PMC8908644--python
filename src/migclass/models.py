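"""Net-squared-displacement model family, least-squares fitting, and
AIC-based behavioural classification.

Planar mode works on NSD in km² (squared straight-line distance from an
origin fix); altitudinal mode works on signed elevation displacement in
metres.  Five a-priori mean curves discriminate the behaviours:

* migrant        — double logistic rising to an asymptote ``delta`` and
                   returning to the origin after a residency ``rho``;
* mixed_migrant  — same, but the return amplitude ``delta2 < delta`` leaves
                   a positive final asymptote (the animal settles near, not
                   at, its origin);
* disperser      — single logistic (one-way shift);
* resident       — constant ``gamma``;
* nomad          — linear ``beta * t`` (the mean NSD of Brownian motion).

The residency parameter ``rho`` is bounded below (default 30 days): an
animal must hold the distant range for at least that long to count as
migratory.  Model selection minimizes AIC = n*ln(RSS/n) + 2*(k+1)
(Gaussian least-squares form, +1 for the error variance); ties break
toward the simpler behaviour in the documented order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.special import expit

from .telemetry import AnimalYear, Fix, RejectLog, Trajectory

PLANAR_MODELS = ("migrant", "mixed_migrant", "resident", "disperser", "nomad")
ALTITUDINAL_MODELS = ("migrant", "resident", "disperser")
# simpler behaviour wins AIC ties, in this order
TIE_BREAK_ORDER = ("resident", "migrant", "mixed_migrant", "disperser", "nomad")

RSS_FLOOR = 1e-10  # keeps ln(RSS/n) finite on exact fits


class UnknownModelError(ValueError):
    pass


@dataclass
class NSDSeries:
    """Displacement series for one animal-year.

    ``mode`` 'planar' carries NSD in km² (value(0)=0 by construction);
    'altitudinal' carries signed elevation displacement in metres.
    ``t`` is days since the start date, strictly increasing.
    """

    animal_id: str
    year_label: int
    mode: str  # 'planar' | 'altitudinal'
    t: np.ndarray
    value: np.ndarray
    origin: Fix
    start_anchor: str = "calving"

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.t.size and np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")
        if self.mode == "planar" and self.value.size and self.value.min() < -1e-9:
            raise ValueError("planar NSD must be non-negative")

    @property
    def n(self) -> int:
        return self.t.size


@dataclass
class ModelParams:
    """Fitted curve parameters; only fields relevant to a model are set.

    Units: delta, delta2, gamma in km² (planar) or m (altitudinal);
    theta, phi1, phi2, rho in days; beta in km²/day.
    """

    delta: Optional[float] = None
    theta: Optional[float] = None
    phi1: Optional[float] = None
    phi2: Optional[float] = None
    rho: Optional[float] = None
    delta2: Optional[float] = None
    gamma: Optional[float] = None
    beta: Optional[float] = None

    def as_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}


@dataclass
class MovementModelFit:
    model_name: str
    params: ModelParams
    rss: float
    n: int
    k: int
    aic: float
    converged: bool
    mode: str = "planar"


@dataclass
class ClassificationResult:
    animal_id: str
    year_label: int
    mode: str
    start_anchor: str
    subset: str
    fits: dict[str, MovementModelFit]
    best_model: str  # 'unclassified' when nothing converged
    delta_aic: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# displacement series
# ---------------------------------------------------------------------------

def _days_since(fixes: Sequence[Fix], origin: Fix) -> np.ndarray:
    t0 = origin.timestamp
    return np.array([(f.timestamp - t0).total_seconds() / 86400.0 for f in fixes])


def compute_nsd(ay: AnimalYear, origin: Optional[Fix] = None,
                start_anchor: str = "calving") -> NSDSeries:
    """Planar NSD: value_i = (x_i - x0)² + (y_i - y0)² in km²."""
    if not ay.fixes:
        raise ValueError("empty animal-year")
    if origin is None:
        origin = ay.fixes[0]
    fixes = [f for f in ay.fixes if f.timestamp >= origin.timestamp]
    t = _days_since(fixes, origin)
    val = np.array([(f.x - origin.x) ** 2 + (f.y - origin.y) ** 2 for f in fixes])
    return NSDSeries(ay.animal_id, ay.year_label, "planar", t, val, origin, start_anchor)


def compute_elevation_displacement(ay: AnimalYear, origin: Optional[Fix] = None,
                                   start_anchor: str = "calving",
                                   log: Optional[RejectLog] = None) -> NSDSeries:
    """Signed elevation displacement (m) relative to the origin fix.

    Fixes lacking elevation are skipped and counted in ``log``.
    """
    if not ay.fixes:
        raise ValueError("empty animal-year")
    log = log if log is not None else RejectLog()
    if origin is None:
        origin = next((f for f in ay.fixes if f.has_elevation), None)
        if origin is None:
            raise ValueError(
                f"{ay.animal_id}: no fixes carry elevation; use planar mode"
            )
    fixes = []
    for f in ay.fixes:
        if f.timestamp < origin.timestamp:
            continue
        if f.has_elevation:
            fixes.append(f)
        else:
            log.add(f"{ay.animal_id}@{f.timestamp}", "missing elevation")
    t = _days_since(fixes, origin)
    val = np.array([f.elevation - origin.elevation for f in fixes])
    return NSDSeries(ay.animal_id, ay.year_label, "altitudinal", t, val, origin,
                     start_anchor)


# ---------------------------------------------------------------------------
# mean curves
# ---------------------------------------------------------------------------

def _double_logistic(t, theta, phi1, phi2, rho):
    """Unit-amplitude rise and (unit) fall; the return midpoint is
    theta2 = theta + 2*phi1 + rho + 2*phi2."""
    theta2 = theta + 2.0 * phi1 + rho + 2.0 * phi2
    up = expit((t - theta) / phi1)
    down = expit((t - theta2) / phi2)
    return up, down


def model_predict(model_name: str, params: ModelParams, t, mode: str = "planar") -> np.ndarray:
    """Expected displacement of ``model_name`` at days ``t``.

    Altitudinal variants add an intercept ``gamma`` (origin elevation error
    then does not bias ``delta``) and allow signed ``delta``.
    """
    t = np.asarray(t, dtype=float)
    p = params
    # gamma doubles as the planar noise-floor intercept when fitted
    offset = p.gamma or 0.0
    if model_name == "migrant":
        up, down = _double_logistic(t, p.theta, p.phi1, p.phi2, p.rho)
        return offset + p.delta * (up - down)
    if model_name == "mixed_migrant":
        up, down = _double_logistic(t, p.theta, p.phi1, p.phi2, p.rho)
        return offset + p.delta * up - p.delta2 * down
    if model_name == "disperser":
        return offset + p.delta * expit((t - p.theta) / p.phi1)
    if model_name == "resident":
        return np.full_like(t, p.gamma)
    if model_name == "nomad":
        return offset + p.beta * t
    raise UnknownModelError(model_name)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class FitConstraints:
    """Bounds and multi-start grid for the nonlinear fits.

    ``rho_min`` is the minimum residency (days) for migratory behaviour.
    ``noise_floor`` adds a non-negative intercept to the planar curves:
    with isotropic positional scatter of sd sigma about the mean path the
    expected NSD is the mean curve plus 2*sigma² everywhere, and without
    the intercept that floor is systematically absorbed by the
    mixed-migrant return amplitude.  ``n_theta_starts``/
    ``extra_delta_starts`` densify the start grid (used by the brute-force
    selection oracle in the tests).
    """

    rho_min: float = 30.0
    phi_bounds: tuple[float, float] = (1.0, 120.0)
    theta_bounds: tuple[float, float] = (0.0, 365.0)
    noise_floor: bool = True
    parsimony_margin: float = 2.0
    n_theta_starts: int = 3
    extra_delta_starts: int = 0
    rho_starts: tuple[float, ...] = (45.0, 100.0)


def _has_intercept(model_name: str, mode: str, floor: bool) -> bool:
    if model_name in ("migrant", "mixed_migrant", "disperser"):
        return mode == "altitudinal" or floor
    if model_name == "nomad":
        return floor
    return False  # resident's gamma is the model itself


def _k_free(model_name: str, mode: str, floor: bool = False) -> int:
    base = {"migrant": 5, "mixed_migrant": 6, "disperser": 3, "resident": 1, "nomad": 1}
    return base[model_name] + int(_has_intercept(model_name, mode, floor))


def _aic(rss: float, n: int, k: int) -> float:
    return n * math.log(max(rss, RSS_FLOOR) / n) + 2.0 * (k + 1)


def _vector_to_params(model_name: str, mode: str, x: np.ndarray,
                      intercept: bool = False) -> ModelParams:
    if model_name == "migrant":
        p = ModelParams(delta=x[0], theta=x[1], phi1=x[2], phi2=x[3], rho=x[4])
    elif model_name == "mixed_migrant":
        p = ModelParams(delta=x[0], theta=x[1], phi1=x[2], phi2=x[3], rho=x[4],
                        delta2=x[5] * x[0])  # x[5] is the fraction delta2/delta
    elif model_name == "disperser":
        p = ModelParams(delta=x[0], theta=x[1], phi1=x[2])
    else:
        raise UnknownModelError(model_name)
    if intercept:
        p.gamma = x[-1]
    return p


def _jacobian(model_name: str, x: np.ndarray, t: np.ndarray,
              intercept: bool) -> np.ndarray:
    """Analytic Jacobian of the sigmoid-model residuals wrt the fit vector."""
    if model_name == "disperser":
        delta, theta, phi1 = x[0], x[1], x[2]
        u = expit((t - theta) / phi1)
        su = u * (1.0 - u)
        cols = [u, -delta * su / phi1, -delta * su * (t - theta) / phi1 ** 2]
    else:
        delta, theta, phi1, phi2, rho = x[0], x[1], x[2], x[3], x[4]
        frac = x[5] if model_name == "mixed_migrant" else 1.0
        theta2 = theta + 2 * phi1 + rho + 2 * phi2
        u = expit((t - theta) / phi1)
        w = expit((t - theta2) / phi2)
        su, sw = u * (1.0 - u), w * (1.0 - w)
        zw = (t - theta2) / phi2
        cols = [
            u - frac * w,                                        # d/d delta
            delta * (-su / phi1 + frac * sw / phi2),             # d/d theta
            delta * (-su * (t - theta) / phi1 ** 2
                     + frac * 2.0 * sw / phi2),                  # d/d phi1
            frac * delta * sw * (zw + 2.0) / phi2,               # d/d phi2
            frac * delta * sw / phi2,                            # d/d rho
        ]
        if model_name == "mixed_migrant":
            cols.append(-delta * w)                              # d/d frac
    if intercept:
        cols.append(np.ones_like(t))
    return np.column_stack(cols)


def _start_grid(model_name: str, mode: str, series: NSDSeries, c: FitConstraints,
                intercept: bool) -> tuple[list[np.ndarray], tuple, tuple]:
    """Documented multi-start grid: theta over evenly spaced year fractions,
    delta over fractions of the observed displacement extreme."""
    t, v = series.t, series.value
    tmax = float(t.max()) if t.size else 365.0
    theta_starts = [tmax * (i + 1) / (c.n_theta_starts + 1) for i in range(c.n_theta_starts)]
    lo_t, hi_t = c.theta_bounds
    theta_starts = [min(max(th, lo_t + 1.0), hi_t - 1.0) for th in theta_starts]

    if mode == "planar":
        vmax = max(float(v.max()), 1e-6)
        amp_starts = [vmax, 0.5 * vmax]
        amp_bounds = (1e-9, 4.0 * vmax)
        # planar intercept = noise floor, estimated from the early quiet part
        g0 = float(np.median(v[: max(5, v.size // 12)]))
        g_lo, g_hi = 0.0, vmax
    else:
        v0 = float(np.median(v[: max(3, v.size // 10)]))
        up, dn = float(v.max()) - v0, float(v.min()) - v0
        amp_starts = [a for a in (up, 0.5 * up, dn, 0.5 * dn) if abs(a) > 1e-6] or [1.0]
        vspan = max(float(v.max()) - float(v.min()), 1e-6)
        amp_bounds = (-4.0 * vspan, 4.0 * vspan)
        g0 = v0
        gspan = max(float(np.abs(v).max()), 1.0)
        g_lo, g_hi = -4.0 * gspan, 4.0 * gspan
    for i in range(c.extra_delta_starts):
        amp_starts.append(amp_starts[0] * (0.25 + 0.1 * i))
    g0 = min(max(g0, g_lo + 1e-9), g_hi - 1e-9)

    phi0 = 10.0
    lo_phi, hi_phi = c.phi_bounds
    starts: list[np.ndarray] = []
    if model_name == "disperser":
        base = [([a, th, phi0]) for th in theta_starts for a in amp_starts]
        lo = [amp_bounds[0], lo_t, lo_phi]
        hi = [amp_bounds[1], hi_t, hi_phi]
    elif model_name == "migrant":
        base = [[a, th, phi0, phi0, max(r0, c.rho_min)]
                for th in theta_starts for a in amp_starts for r0 in c.rho_starts]
        lo = [amp_bounds[0], lo_t, lo_phi, lo_phi, c.rho_min]
        hi = [amp_bounds[1], hi_t, hi_phi, hi_phi, 365.0]
    elif model_name == "mixed_migrant":
        base = [[a, th, phi0, phi0, max(r0, c.rho_min), 0.7]
                for th in theta_starts for a in amp_starts for r0 in c.rho_starts]
        lo = [amp_bounds[0], lo_t, lo_phi, lo_phi, c.rho_min, 1e-3]
        hi = [amp_bounds[1], hi_t, hi_phi, hi_phi, 365.0, 0.999]
    else:
        raise UnknownModelError(model_name)
    if intercept:
        base = [b + [g0] for b in base]
        lo, hi = lo + [g_lo], hi + [g_hi]
    starts = [np.array(b, dtype=float) for b in base]
    return starts, tuple(lo), tuple(hi)


def fit_model(series: NSDSeries, model_name: str,
              constraints: Optional[FitConstraints] = None) -> MovementModelFit:
    """Least-squares fit of one candidate model to a displacement series.

    Resident and nomad have closed-form solutions; the sigmoidal models use
    bounded trust-region least squares from a deterministic multi-start
    grid, keeping the lowest-RSS converged solution.  On total optimizer
    failure the fit is returned with ``converged=False`` and ``aic=+inf``
    so selection skips it.
    """
    c = constraints or FitConstraints()
    mode = series.mode
    floor = c.noise_floor and mode == "planar"
    intercept = _has_intercept(model_name, mode, floor)
    t, v = series.t, series.value
    n = series.n
    k = _k_free(model_name, mode, floor)
    if n < k + 2:
        raise ValueError(f"need at least {k + 2} points to fit {model_name}, got {n}")

    if model_name == "resident":
        gamma = float(v.mean())
        rss = float(((v - gamma) ** 2).sum())
        return MovementModelFit(model_name, ModelParams(gamma=gamma), rss, n, k,
                                _aic(rss, n, k), True, mode)
    if model_name == "nomad":
        if mode == "altitudinal":
            raise UnknownModelError("nomad is not an altitudinal candidate")
        denom = float((t * t).sum())
        if intercept:
            A = np.column_stack([np.ones_like(t), t])
            (gamma, beta), *_ = np.linalg.lstsq(A, v, rcond=None)
            if gamma < 0:  # floor is non-negative; fall back to the origin line
                gamma, beta = 0.0, float((t * v).sum() / denom) if denom > 0 else 0.0
            params = ModelParams(beta=float(beta), gamma=float(gamma))
            rss = float(((v - gamma - beta * t) ** 2).sum())
        else:
            beta = float((t * v).sum() / denom) if denom > 0 else 0.0
            params = ModelParams(beta=beta)
            rss = float(((v - beta * t) ** 2).sum())
        return MovementModelFit(model_name, params, rss, n, k,
                                _aic(rss, n, k), True, mode)

    starts, lo, hi = _start_grid(model_name, mode, series, c, intercept)

    def resid(x):
        return model_predict(
            model_name, _vector_to_params(model_name, mode, x, intercept), t, mode) - v

    def jac(x):
        return _jacobian(model_name, x, t, intercept)

    best: Optional[tuple[float, np.ndarray]] = None
    for x0 in starts:
        x0 = np.clip(x0, np.asarray(lo) + 1e-12, np.asarray(hi) - 1e-12)
        try:
            sol = least_squares(resid, x0, jac=jac, bounds=(lo, hi), method="trf",
                                xtol=1e-10, ftol=1e-10, gtol=1e-10, max_nfev=500)
        except Exception:
            continue
        if not np.all(np.isfinite(sol.x)):
            continue
        rss = float((sol.fun ** 2).sum())
        if best is None or rss < best[0]:
            best = (rss, sol.x)
    if best is None:
        return MovementModelFit(model_name, ModelParams(), math.inf, n, k,
                                math.inf, False, mode)
    rss, x = best
    return MovementModelFit(model_name, _vector_to_params(model_name, mode, x, intercept),
                            rss, n, k, _aic(rss, n, k), True, mode)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def candidate_models(mode: str, subset: str) -> tuple[str, ...]:
    if subset == "binary":
        return ("migrant", "resident")
    if mode == "altitudinal":
        if subset in ("all", "no_nomad"):
            return ALTITUDINAL_MODELS
        raise ValueError(f"unknown subset {subset!r}")
    if subset == "all":
        return PLANAR_MODELS
    if subset == "no_nomad":
        return ("migrant", "mixed_migrant", "resident", "disperser")
    raise ValueError(f"unknown subset {subset!r}")


def select_best(fits: dict[str, MovementModelFit],
                parsimony_margin: float = 2.0) -> Optional[str]:
    """AIC selection with a parsimony band: among converged fits whose AIC
    lies within ``parsimony_margin`` of the minimum (the conventional
    "equally supported" band), the model with the fewest free parameters
    wins; equal parameter counts resolve by the documented behaviour
    order.  ``parsimony_margin=0`` reduces to the strict argmin with
    deterministic tie-breaks."""
    converged = {m: f for m, f in fits.items() if f.converged and math.isfinite(f.aic)}
    if not converged:
        return None
    aic_min = min(f.aic for f in converged.values())
    band = [m for m, f in converged.items() if f.aic <= aic_min + parsimony_margin]
    return min(band, key=lambda m: (converged[m].k, TIE_BREAK_ORDER.index(m)))


def classify(series: NSDSeries, subset: str = "all",
             constraints: Optional[FitConstraints] = None) -> ClassificationResult:
    """Fit every candidate model and pick the best by AIC.

    Models within the parsimony margin (default 2 AIC units, the
    conventional "equally supported" band) of the minimum resolve toward
    the simpler behaviour in the order resident < migrant < mixed_migrant
    < disperser < nomad; exact ties break the same way.  If no model
    converges the result is 'unclassified'.
    """
    c = constraints or FitConstraints()
    fits = {m: fit_model(series, m, c) for m in candidate_models(series.mode, subset)}
    best_name = select_best(fits, c.parsimony_margin)
    if best_name is None:
        return ClassificationResult(series.animal_id, series.year_label, series.mode,
                                    series.start_anchor, subset, fits, "unclassified")
    converged = {m: f for m, f in fits.items() if f.converged and math.isfinite(f.aic)}
    aic_min = min(f.aic for f in converged.values())
    delta = {m: f.aic - aic_min for m, f in converged.items()}
    return ClassificationResult(series.animal_id, series.year_label, series.mode,
                                series.start_anchor, subset, fits, best_name, delta)


# ---------------------------------------------------------------------------
# start selection (rNSD) and derived quantities
# ---------------------------------------------------------------------------

@dataclass
class StartSelection:
    anchor: tuple[int, int]
    origin: Fix
    start_date: date
    best_aic: float = math.nan


def select_start(traj: Trajectory, candidate_anchors: Sequence[tuple[int, int]],
                 rnsd: bool = False, scan_days: int = 30, subset: str = "all",
                 constraints: Optional[FitConstraints] = None,
                 max_anchor_gap_days: int = 14, score: str = "medoid",
                 log: Optional[RejectLog] = None) -> list[StartSelection]:
    """Choose the NSD origin fix for each candidate start anchor.

    With ``rnsd=False`` the origin is the first fix on/after the anchor
    date.  With ``rnsd=True`` (relative NSD) every fix in the first
    ``scan_days`` days after the anchor is a candidate origin and the
    series is re-referenced to the best one.  Two scores are offered:

    * ``'medoid'`` (default): the fix closest to the scan-window centroid,
      i.e. minimizing the summed squared displacement to the other window
      fixes.  Because NSD noise variance grows with NSD itself, scoring
      whole-year model fits favours origins displaced toward the migratory
      heading and biases the distance estimate low; the medoid score is
      immune to that and costs no model fits.
    * ``'aic'``: classify from each candidate origin and keep the origin
      whose best-model AIC is lowest.

    Anchors with no fix within ``max_anchor_gap_days`` are skipped and
    logged.
    """
    log = log if log is not None else RejectLog()
    out = []
    if not traj.fixes:
        return out
    first_date = traj.fixes[0].timestamp.date()
    for anchor in candidate_anchors:
        from .telemetry import _anchor_on_or_before
        anchor_date = _anchor_on_or_before(first_date, anchor)
        cands: list[Fix] = []
        for _ in range(2):  # retry the next calendar occurrence once
            cands = [f for f in traj.fixes
                     if anchor_date <= f.timestamp.date()
                     < anchor_date + timedelta(days=scan_days)]
            if cands and (cands[0].timestamp.date() - anchor_date).days <= max_anchor_gap_days:
                break
            anchor_date = date(anchor_date.year + 1, anchor[0], anchor[1])
            cands = []
        if not cands:
            log.add(f"{traj.animal_id}/{anchor}",
                    f"no fix within {max_anchor_gap_days} d of anchor")
            continue
        if not rnsd:
            out.append(StartSelection(anchor, cands[0], anchor_date))
            continue
        if score == "medoid":
            xy = np.array([[f.x, f.y] for f in cands])
            cx, cy = xy.mean(axis=0)
            i = int(np.argmin((xy[:, 0] - cx) ** 2 + (xy[:, 1] - cy) ** 2))
            out.append(StartSelection(anchor, cands[i], anchor_date))
            continue
        if score != "aic":
            raise ValueError(f"unknown rNSD score {score!r}")
        best: Optional[StartSelection] = None
        for origin in cands:
            ay = AnimalYear(traj.animal_id, anchor_date.year, anchor_date,
                            [f for f in traj.fixes if f.timestamp >= origin.timestamp])
            series = compute_nsd(ay, origin)
            res = classify(series, subset, constraints)
            if res.best_model == "unclassified":
                continue
            aic = res.fits[res.best_model].aic
            if best is None or aic < best.best_aic:
                best = StartSelection(anchor, origin, anchor_date, aic)
        if best is not None:
            out.append(best)
    return out


def migration_distance(fit: MovementModelFit) -> float:
    """One-way migration distance in km: sqrt(delta) of a planar
    migrant/mixed-migrant fit."""
    if fit.mode != "planar":
        raise ValueError("migration distance is defined for planar fits only")
    if fit.model_name not in ("migrant", "mixed_migrant"):
        raise ValueError(f"migration distance undefined for {fit.model_name!r}")
    return math.sqrt(fit.params.delta)
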