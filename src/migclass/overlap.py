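"""Seasonal utilization distributions, 95% isopleths, and the overlap index.

Seasonal ranges are estimated by fixed-kernel density estimation with the
reference (normal-rule) bandwidth, h = sqrt((var_x + var_y)/2) * n^(-1/6),
applied as a single scalar on both axes.  The 95% isopleth is the smallest
set of grid cells holding 95% of the UD mass; its area (cell count x cell
area) gives the seasonal range area.  Winter/summer overlap is quantified
by the index

    IO = 2 * A12 / (A1 + A2)

where A1 and A2 are the summer and winter isopleth areas (km²) and A12
their intersection.  IO = 0 marks a "clear migrant" (fully separated
seasonal ranges); IO = 1, identical ranges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date
from typing import Optional, Sequence

import numpy as np

from .telemetry import Fix, RejectLog, Trajectory

MIN_FIXES_PER_SEASON = 30


class NotEnoughFixesError(ValueError):
    pass


# ---------------------------------------------------------------------------
# season windows
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SeasonWindow:
    """Inclusive month-day window; ``end`` before ``start`` wraps the year
    boundary (winter)."""

    name: str
    start: tuple[int, int]
    end: tuple[int, int]

    def contains(self, d: date) -> bool:
        md = (d.month, d.day)
        if self.start <= self.end:
            return self.start <= md <= self.end
        return md >= self.start or md <= self.end


SUMMER = SeasonWindow("summer", (7, 1), (9, 15))
WINTER = SeasonWindow("winter", (12, 1), (4, 30))


def season_filter(traj: Trajectory, window: SeasonWindow,
                  pairing_rule: str = "pooled") -> list[Fix]:
    """Fixes falling inside the seasonal window (endpoints inclusive).

    ``pairing_rule='pooled'`` pools every year of data into one seasonal
    sample per animal (one IO per individual); a (name, year) tuple rule is
    handled by :func:`seasonal_fixes_by_year`.
    """
    if pairing_rule != "pooled":
        raise ValueError("season_filter handles the pooled rule; use "
                         "seasonal_fixes_by_year for per-year pairing")
    return [f for f in traj.fixes if window.contains(f.timestamp.date())]


def seasonal_fixes_by_year(traj: Trajectory, window: SeasonWindow) -> dict[int, list[Fix]]:
    """Per-year seasonal samples.  A winter spanning the year boundary is
    labelled by the year in which it begins (Dec of year Y pairs with the
    summer of year Y)."""
    out: dict[int, list[Fix]] = {}
    for f in traj.fixes:
        d = f.timestamp.date()
        if not window.contains(d):
            continue
        year = d.year
        if window.start > window.end and (d.month, d.day) <= window.end:
            year -= 1  # Jan-Apr belongs to the winter that began the year before
        out.setdefault(year, []).append(f)
    return out


# ---------------------------------------------------------------------------
# gridded kernel UD
# ---------------------------------------------------------------------------

@dataclass
class GridSpec:
    """UD grid geometry: ``cell_km`` (None = extent/``n_cells_default``) and
    the margin in bandwidths beyond the data hull."""

    cell_km: Optional[float] = None
    n_cells_default: int = 50
    margin_bandwidths: float = 3.0


@dataclass
class UD:
    """Normalized gridded utilization distribution (cell masses sum to 1)."""

    x: np.ndarray  # cell-centre coordinates, km
    y: np.ndarray
    density: np.ndarray  # shape (len(y), len(x)), probability per km²
    cell_km: float
    bandwidth_km: float

    @property
    def cell_area(self) -> float:
        return self.cell_km ** 2

    @property
    def mass(self) -> np.ndarray:
        return self.density * self.cell_area


def reference_bandwidth(xy: np.ndarray) -> float:
    """Normal-rule scalar bandwidth: sqrt((var_x+var_y)/2) * n^(-1/6)."""
    n = xy.shape[0]
    vx, vy = np.var(xy[:, 0], ddof=1), np.var(xy[:, 1], ddof=1)
    return math.sqrt((vx + vy) / 2.0) * n ** (-1.0 / 6.0)


def _grid_axes(xy: np.ndarray, h: float, spec: GridSpec,
               extent: Optional[tuple[float, float, float, float]] = None):
    if extent is None:
        x0, x1 = xy[:, 0].min(), xy[:, 0].max()
        y0, y1 = xy[:, 1].min(), xy[:, 1].max()
    else:
        x0, x1, y0, y1 = extent
    m = spec.margin_bandwidths * h
    x0, x1, y0, y1 = x0 - m, x1 + m, y0 - m, y1 + m
    cell = spec.cell_km
    if cell is None:
        cell = max(x1 - x0, y1 - y0) / spec.n_cells_default
    xs = np.arange(x0 + cell / 2, x1, cell)
    ys = np.arange(y0 + cell / 2, y1, cell)
    return xs, ys, cell


def estimate_ud(fixes_or_xy, grid: Optional[GridSpec] = None,
                min_fixes: int = MIN_FIXES_PER_SEASON,
                bandwidth_km: Optional[float] = None,
                extent: Optional[tuple[float, float, float, float]] = None) -> UD:
    """Fixed-kernel (bivariate Gaussian) UD on a regular grid.

    The grid extends at least ``margin_bandwidths`` bandwidths beyond the
    data hull and the discrete mass is renormalized to 1.  Fewer than
    ``min_fixes`` locations raises :class:`NotEnoughFixesError`; zero
    spatial variance (all fixes identical) is an error.
    """
    grid = grid or GridSpec()
    if isinstance(fixes_or_xy, np.ndarray):
        xy = np.asarray(fixes_or_xy, dtype=float)
    else:
        xy = np.array([[f.x, f.y] for f in fixes_or_xy], dtype=float)
    n = xy.shape[0]
    if n < min_fixes:
        raise NotEnoughFixesError(f"{n} fixes < required {min_fixes}")
    h = bandwidth_km if bandwidth_km is not None else reference_bandwidth(xy)
    if h <= 0 or not math.isfinite(h):
        raise ValueError("zero spatial variance: kernel bandwidth undefined")
    xs, ys, cell = _grid_axes(xy, h, grid, extent)
    # Gaussian kernel evaluated separably then combined: O(n * (nx + ny)) exp calls
    kx = np.exp(-0.5 * ((xs[None, :] - xy[:, 0][:, None]) / h) ** 2)
    ky = np.exp(-0.5 * ((ys[None, :] - xy[:, 1][:, None]) / h) ** 2)
    dens = np.einsum("ni,nj->ij", ky, kx) / (n * 2.0 * math.pi * h * h)
    total = dens.sum() * cell * cell
    dens /= total
    return UD(xs, ys, dens, cell, h)


def isopleth(ud: UD, level: float = 0.95) -> tuple[np.ndarray, float]:
    """Smallest-cell-count region holding >= ``level`` of the UD mass.

    Cells are taken in descending density order; ties break by flattened
    cell index (deterministic).  Returns the boolean membership mask and
    the region area in km².
    """
    mass = ud.mass.ravel()
    order = np.argsort(-mass, kind="stable")
    csum = np.cumsum(mass[order])
    # first index where cumulative mass reaches the level (tolerate fp slack)
    k = int(np.searchsorted(csum, level - 1e-12)) + 1
    k = min(k, mass.size)
    mask = np.zeros(mass.size, dtype=bool)
    mask[order[:k]] = True
    return mask.reshape(ud.density.shape), k * ud.cell_area


# ---------------------------------------------------------------------------
# seasonal ranges and the overlap index
# ---------------------------------------------------------------------------

@dataclass
class SeasonalRange:
    animal_id: str
    season: str
    n_fixes: int
    ud: UD
    isopleth_mask: np.ndarray
    area: float  # km²
    xy: Optional[np.ndarray] = None  # retained for re-rasterization


@dataclass
class OverlapResult:
    animal_id: str
    A1: float  # summer isopleth area, km²
    A2: float  # winter isopleth area, km²
    A12: float  # intersection area, km²
    io: float
    clear_migrant: bool


def seasonal_range(animal_id: str, season: str, fixes: Sequence[Fix],
                   grid: Optional[GridSpec] = None, level: float = 0.95,
                   extent=None, cell_km=None) -> SeasonalRange:
    xy = np.array([[f.x, f.y] for f in fixes], dtype=float)
    g = grid or GridSpec()
    if cell_km is not None:
        g = GridSpec(cell_km=cell_km, margin_bandwidths=g.margin_bandwidths)
    ud = estimate_ud(xy, g, extent=extent)
    mask, area = isopleth(ud, level)
    return SeasonalRange(animal_id, season, xy.shape[0], ud, mask, area, xy)


def _grids_match(a: UD, b: UD) -> bool:
    return (a.x.shape == b.x.shape and a.y.shape == b.y.shape
            and np.allclose(a.x, b.x) and np.allclose(a.y, b.y))


def index_overlap(summer: SeasonalRange, winter: SeasonalRange,
                  level: float = 0.95) -> OverlapResult:
    """IO = 2*A12/(A1+A2) between summer and winter 95% isopleths.

    Ranges estimated on different grids are re-rasterized onto a common
    grid (union extent, finer cell, each season keeping its own bandwidth)
    from the retained fixes before intersecting.
    """
    if not _grids_match(summer.ud, winter.ud):
        if summer.xy is None or winter.xy is None:
            raise ValueError("ranges on different grids and no fixes retained")
        allxy = np.vstack([summer.xy, winter.xy])
        hs = reference_bandwidth(summer.xy)
        hw = reference_bandwidth(winter.xy)
        m = 3.0 * max(hs, hw)
        extent = (allxy[:, 0].min() - m, allxy[:, 0].max() + m,
                  allxy[:, 1].min() - m, allxy[:, 1].max() + m)
        cell = min(summer.ud.cell_km, winter.ud.cell_km)
        g = GridSpec(cell_km=cell, margin_bandwidths=0.0)
        uds = estimate_ud(summer.xy, g, bandwidth_km=hs, extent=extent)
        udw = estimate_ud(winter.xy, g, bandwidth_km=hw, extent=extent)
        ms, a1 = isopleth(uds, level)
        mw, a2 = isopleth(udw, level)
        cell_area = uds.cell_area
    else:
        ms, a1 = summer.isopleth_mask, summer.area
        mw, a2 = winter.isopleth_mask, winter.area
        cell_area = summer.ud.cell_area
    a12 = float((ms & mw).sum()) * cell_area
    io = 2.0 * a12 / (a1 + a2)
    return OverlapResult(summer.animal_id, a1, a2, a12, io, a12 == 0.0)


def overlap_for_animal(traj: Trajectory, summer: SeasonWindow = SUMMER,
                       winter: SeasonWindow = WINTER,
                       grid: Optional[GridSpec] = None, level: float = 0.95,
                       min_fixes: int = MIN_FIXES_PER_SEASON,
                       log: Optional[RejectLog] = None) -> Optional[OverlapResult]:
    """Pooled per-animal seasonal overlap on a shared grid.

    Animals lacking ``min_fixes`` locations in either season are excluded
    with a logged reason (returns None).
    """
    log = log if log is not None else RejectLog()
    sfix = season_filter(traj, summer)
    wfix = season_filter(traj, winter)
    for name, fx in (("summer", sfix), ("winter", wfix)):
        if len(fx) < min_fixes:
            log.add(traj.animal_id, f"{len(fx)} {name} fixes < {min_fixes}")
            return None
    sxy = np.array([[f.x, f.y] for f in sfix])
    wxy = np.array([[f.x, f.y] for f in wfix])
    hs, hw = reference_bandwidth(sxy), reference_bandwidth(wxy)
    allxy = np.vstack([sxy, wxy])
    m = (grid or GridSpec()).margin_bandwidths * max(hs, hw)
    extent = (allxy[:, 0].min() - m, allxy[:, 0].max() + m,
              allxy[:, 1].min() - m, allxy[:, 1].max() + m)
    span = max(extent[1] - extent[0], extent[3] - extent[2])
    cell = (grid.cell_km if grid and grid.cell_km else
            span / (grid or GridSpec()).n_cells_default)
    g = GridSpec(cell_km=cell, margin_bandwidths=0.0)
    uds = estimate_ud(sxy, g, min_fixes, bandwidth_km=hs, extent=extent)
    udw = estimate_ud(wxy, g, min_fixes, bandwidth_km=hw, extent=extent)
    ms, a1 = isopleth(uds, level)
    mw, a2 = isopleth(udw, level)
    a12 = float((ms & mw).sum()) * uds.cell_area
    io = 2.0 * a12 / (a1 + a2)
    return OverlapResult(traj.animal_id, a1, a2, a12, io, a12 == 0.0)
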