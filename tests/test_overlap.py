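"""Kernel UDs, isopleths, and the seasonal overlap index IO."""

import math
from datetime import date, datetime, timedelta

import numpy as np
import pytest

import migclass as mc
from migclass.overlap import (UD, GridSpec, NotEnoughFixesError,
                              reference_bandwidth)


def uniform_square_range(x0, y0, side=1.0, cell=0.02, animal_id="a",
                         season="summer", grid_origin=(0.0, 0.0),
                         grid_span=4.0, level=0.95):
    """A SeasonalRange whose UD is uniform over a square on a shared grid."""
    xs = np.arange(grid_origin[0] + cell / 2, grid_origin[0] + grid_span, cell)
    ys = np.arange(grid_origin[1] + cell / 2, grid_origin[1] + grid_span, cell)
    X, Y = np.meshgrid(xs, ys)
    inside = ((X >= x0) & (X < x0 + side) & (Y >= y0) & (Y < y0 + side))
    dens = inside / (inside.sum() * cell * cell)
    ud = UD(xs, ys, dens, cell, bandwidth_km=math.nan)
    mask, area = mc.isopleth(ud, level)
    return mc.SeasonalRange(animal_id, season, 99, ud, mask, area)


class TestSeasonWindows:
    def test_summer_endpoints_inclusive(self):
        assert mc.SUMMER.contains(date(2001, 9, 15))
        assert mc.SUMMER.contains(date(2001, 7, 1))
        assert not mc.SUMMER.contains(date(2001, 9, 16))

    def test_winter_wraps_year_boundary(self):
        assert mc.WINTER.contains(date(2001, 12, 1))
        assert mc.WINTER.contains(date(2002, 4, 30))
        assert not mc.WINTER.contains(date(2002, 5, 1))

    def test_pooled_filter_and_per_year_pairing(self):
        fixes = [mc.Fix("a", datetime(2000, 12, 1, 12), x=0, y=0),
                 mc.Fix("a", datetime(2001, 4, 30, 12), x=0, y=0),
                 mc.Fix("a", datetime(2001, 8, 1, 12), x=0, y=0)]
        traj = mc.Trajectory("a", fixes)
        assert len(mc.season_filter(traj, mc.WINTER)) == 2
        by_year = mc.seasonal_fixes_by_year(traj, mc.WINTER)
        assert list(by_year) == [2000] and len(by_year[2000]) == 2


class TestEstimateUD:
    def test_mass_normalized(self):
        rng = np.random.default_rng(0)
        ud = mc.estimate_ud(rng.normal(0, 2, (60, 2)))
        assert ud.mass.sum() == pytest.approx(1.0, abs=1e-6)

    def test_gaussian_sample_mass_within_95pct_radius(self):
        rng = np.random.default_rng(7)
        xy = rng.normal(0.0, 1.0, (1000, 2))
        ud = mc.estimate_ud(xy, GridSpec(cell_km=0.1))
        X, Y = np.meshgrid(ud.x, ud.y)
        r95 = math.sqrt(5.991)  # chi2(2) 95% quantile radius for sigma=1
        mu = xy.mean(axis=0)
        inside = np.hypot(X - mu[0], Y - mu[1]) <= r95
        assert ud.mass[inside].sum() == pytest.approx(0.95, abs=0.02)

    def test_reference_bandwidth_rule(self):
        rng = np.random.default_rng(1)
        xy = rng.normal(0, 3, (100, 2))
        h = reference_bandwidth(xy)
        expect = math.sqrt((xy[:, 0].var(ddof=1) + xy[:, 1].var(ddof=1)) / 2) \
            * 100 ** (-1 / 6)
        assert h == pytest.approx(expect)

    def test_fewer_than_30_fixes_rejected(self):
        rng = np.random.default_rng(2)
        with pytest.raises(NotEnoughFixesError):
            mc.estimate_ud(rng.normal(0, 1, (29, 2)))

    def test_zero_variance_is_an_error(self):
        with pytest.raises(ValueError):
            mc.estimate_ud(np.zeros((40, 2)))


class TestIsopleth:
    def test_uniform_ud_takes_95_of_100_cells(self):
        xs = np.arange(0.5, 10.5)
        dens = np.full((10, 10), 0.01)
        ud = UD(xs, xs, dens, 1.0, 1.0)
        _, area = mc.isopleth(ud, 0.95)
        assert area == 95.0

    def test_level_one_takes_full_support(self):
        xs = np.arange(0.5, 10.5)
        dens = np.full((10, 10), 0.01)
        ud = UD(xs, xs, dens, 1.0, 1.0)
        _, area = mc.isopleth(ud, 1.0)
        assert area == 100.0

    def test_area_non_decreasing_in_level(self):
        rng = np.random.default_rng(3)
        ud = mc.estimate_ud(rng.normal(0, 1, (200, 2)), GridSpec(cell_km=0.1))
        areas = [mc.isopleth(ud, lv)[1] for lv in (0.5, 0.8, 0.9, 0.95, 0.99)]
        assert all(a <= b for a, b in zip(areas, areas[1:]))

    def test_gaussian_ud_isopleth_matches_analytic_ellipse(self):
        # 95% contour of an isotropic Gaussian (sigma=1 km) has area pi*5.991
        cell = 0.05
        xs = np.arange(-5 + cell / 2, 5, cell)
        X, Y = np.meshgrid(xs, xs)
        dens = np.exp(-(X ** 2 + Y ** 2) / 2) / (2 * math.pi)
        dens /= dens.sum() * cell * cell
        _, area = mc.isopleth(UD(xs, xs, dens, cell, 1.0), 0.95)
        assert area == pytest.approx(math.pi * 5.991, rel=0.05)


class TestIndexOverlap:
    def test_identical_ranges_give_io_one(self):
        a = uniform_square_range(1.0, 1.0)
        b = uniform_square_range(1.0, 1.0, season="winter")
        res = mc.index_overlap(a, b)
        assert res.io == pytest.approx(1.0, abs=1e-6)
        assert not res.clear_migrant

    def test_disjoint_ranges_are_clear_migrants(self):
        a = uniform_square_range(0.0, 0.0)
        b = uniform_square_range(2.5, 2.5, season="winter")
        res = mc.index_overlap(a, b)
        assert res.io == 0.0 and res.clear_migrant

    def test_half_overlap_arithmetic(self):
        a = uniform_square_range(1.0, 1.0, level=1.0)
        b = uniform_square_range(1.5, 1.0, season="winter", level=1.0)
        res = mc.index_overlap(a, b)
        assert res.A1 == pytest.approx(1.0, rel=0.01)
        assert res.A12 == pytest.approx(0.5, rel=0.03)
        assert res.io == pytest.approx(0.5, abs=0.02)

    @pytest.mark.parametrize("f", [0.0, 0.25, 0.5, 0.75, 1.0])
    def test_translated_squares_match_polygon_oracle(self, f):
        from shapely.geometry import box
        shift = 1.0 - f
        a = uniform_square_range(1.0, 1.0)
        b = uniform_square_range(1.0 + shift, 1.0, season="winter")
        res = mc.index_overlap(a, b)
        pa, pb = box(1, 1, 2, 2), box(1 + shift, 1, 2 + shift, 2)
        oracle = 2 * pa.intersection(pb).area / (pa.area + pb.area)
        assert res.io == pytest.approx(oracle, abs=0.02)

    def test_io_symmetric_and_translation_invariant(self):
        rng = np.random.default_rng(5)
        s_xy = rng.normal(0, 1, (60, 2))
        w_xy = rng.normal(1.0, 1.2, (60, 2))

        def build(xy, season, offset=0.0):
            f = [mc.Fix("a", datetime(2000, 1, 1) + timedelta(days=i),
                        x=float(x + offset), y=float(y + offset))
                 for i, (x, y) in enumerate(xy)]
            return f

        traj = mc.Trajectory("a", [])
        res1 = mc.index_overlap(
            mc.seasonal_range("a", "summer", build(s_xy, "s")),
            mc.seasonal_range("a", "winter", build(w_xy, "w")))
        res_swap = mc.index_overlap(
            mc.seasonal_range("a", "winter", build(w_xy, "w")),
            mc.seasonal_range("a", "summer", build(s_xy, "s")))
        res_shift = mc.index_overlap(
            mc.seasonal_range("a", "summer", build(s_xy, "s", 100.0)),
            mc.seasonal_range("a", "winter", build(w_xy, "w", 100.0)))
        assert res1.io == pytest.approx(res_swap.io, abs=1e-9)
        assert res1.io == pytest.approx(res_shift.io, abs=1e-6)


class TestOverlapForAnimal:
    @staticmethod
    def _winter_resident_spec(**kw):
        # residency spanning Dec-Apr so the far range covers the winter window
        return mc.BehaviourSpec("migrant", departure_day=160.0,
                                transition_days=7.0, residency_days=170.0, **kw)

    def test_true_migrant_has_separated_seasonal_ranges(self):
        traj, _ = mc.simulate_year(self._winter_resident_spec(home_sd_km=2.0), 21)
        res = mc.overlap_for_animal(traj)
        assert res is not None
        assert res.io == 0.0 and res.clear_migrant

    def test_resident_ranges_overlap_strongly(self):
        traj, _ = mc.simulate_year(mc.BehaviourSpec("resident", home_sd_km=2.0), 22)
        res = mc.overlap_for_animal(traj)
        assert res.io > 0.5

    def test_sparse_season_excluded_with_reason(self):
        traj, _ = mc.simulate_year(mc.BehaviourSpec("resident", home_sd_km=2.0), 23)
        summer_only = mc.Trajectory(traj.animal_id, traj.fixes[:120])
        log = mc.RejectLog()
        assert mc.overlap_for_animal(summer_only, log=log) is None
        assert log.n == 1 and "winter" in log.records[0][1]
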