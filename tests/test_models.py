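"""Displacement series, model curves, fitting, and AIC classification."""

import math
from datetime import datetime, timedelta

import numpy as np
import pytest

import migclass as mc
from migclass.models import NSDSeries, UnknownModelError, select_best

from conftest import make_animal_year, true_origin_fix


def series_from(t, value, mode="planar"):
    origin = mc.Fix("a", datetime(2000, 6, 1, 12), x=0.0, y=0.0, elevation=800.0)
    return NSDSeries("a", 2000, mode, np.asarray(t, float),
                     np.asarray(value, float), origin)


def daily_fixes(values_xy, elev=None, start=datetime(2000, 6, 1, 12)):
    return [mc.Fix("a", start + timedelta(days=i), x=float(x), y=float(y),
                   elevation=float(elev[i]) if elev is not None else math.nan)
            for i, (x, y) in enumerate(values_xy)]


class TestComputeNSD:
    def test_origin_and_pythagorean_values(self):
        fixes = daily_fixes([(0.0, 0.0), (3.0, 4.0)])
        ay = mc.AnimalYear("a", 2000, fixes[0].timestamp.date(), fixes)
        s = mc.compute_nsd(ay)
        assert s.value[0] == 0.0
        assert s.value[1] == 25.0

    def test_empty_year_is_an_error(self):
        ay = mc.AnimalYear("a", 2000, None, [])
        with pytest.raises(ValueError):
            mc.compute_nsd(ay)

    def test_noise_free_migrant_peaks_at_distance_squared(self,
                                                          noise_free_trajectories):
        _, traj, _ = noise_free_trajectories["migrant"]
        s = mc.compute_nsd(make_animal_year(traj), true_origin_fix(traj))
        assert abs(s.value.max() - 2500.0) < 10.0  # plateau ~99.6% of delta


class TestElevationDisplacement:
    def test_signed_displacement(self):
        fixes = daily_fixes([(0, 0), (1, 0)], elev=[800.0, 1300.0])
        ay = mc.AnimalYear("a", 2000, fixes[0].timestamp.date(), fixes)
        s = mc.compute_elevation_displacement(ay)
        assert s.value.tolist() == [0.0, 500.0]

    def test_constant_elevation_gives_zeros(self):
        fixes = daily_fixes([(0, 0)] * 5, elev=[900.0] * 5)
        ay = mc.AnimalYear("a", 2000, fixes[0].timestamp.date(), fixes)
        assert np.all(mc.compute_elevation_displacement(ay).value == 0.0)

    def test_missing_elevation_everywhere_directs_to_planar(self):
        fixes = daily_fixes([(0, 0), (1, 1)])
        ay = mc.AnimalYear("a", 2000, fixes[0].timestamp.date(), fixes)
        with pytest.raises(ValueError, match="planar"):
            mc.compute_elevation_displacement(ay)

    def test_fixes_without_elevation_skipped_and_counted(self):
        elev = [800.0, math.nan, 900.0]
        fixes = daily_fixes([(0, 0)] * 3, elev=elev)
        ay = mc.AnimalYear("a", 2000, fixes[0].timestamp.date(), fixes)
        log = mc.RejectLog()
        s = mc.compute_elevation_displacement(ay, log=log)
        assert s.n == 2 and log.n == 1


class TestModelPredict:
    def test_resident_constant(self):
        p = mc.ModelParams(gamma=25.0)
        assert np.all(mc.model_predict("resident", p, [0, 100, 364]) == 25.0)

    def test_nomad_linear(self):
        assert mc.model_predict("nomad", mc.ModelParams(beta=4.0), [10.0]) == 40.0

    def test_migrant_midpoint_is_half_amplitude(self):
        p = mc.ModelParams(delta=2500.0, theta=150.0, phi1=5.0, phi2=5.0, rho=60.0)
        # at t = theta the rising logistic is delta/2; the return term at
        # theta2 - t = 80 = 16*phi2 contributes ~delta*1.1e-7
        val = mc.model_predict("migrant", p, [150.0])[0]
        assert abs(val - 1250.0) < 0.001

    def test_mixed_migrant_keeps_positive_final_asymptote(self):
        p = mc.ModelParams(delta=2500.0, theta=150.0, phi1=5.0, phi2=5.0,
                           rho=60.0, delta2=2275.0)
        tail = mc.model_predict("mixed_migrant", p, [5000.0])[0]
        assert abs(tail - 225.0) < 1e-6
        migrant_tail = mc.model_predict(
            "migrant", mc.ModelParams(delta=2500.0, theta=150.0, phi1=5.0,
                                      phi2=5.0, rho=60.0), [5000.0])[0]
        assert migrant_tail < 1e-6  # full migrant returns to the origin

    def test_unknown_model_errors(self):
        with pytest.raises(UnknownModelError):
            mc.model_predict("martian", mc.ModelParams(), [0.0])


class TestFitModel:
    def test_constant_series_resident_exact(self):
        s = series_from(np.arange(365.0), np.full(365, 25.0))
        f = mc.fit_model(s, "resident")
        assert f.params.gamma == pytest.approx(25.0)
        assert f.rss == pytest.approx(0.0, abs=1e-12)

    def test_linear_series_nomad_exact(self):
        t = np.arange(365.0)
        f = mc.fit_model(series_from(t, 4.0 * t), "nomad")
        assert f.params.beta == pytest.approx(4.0)
        assert f.rss == pytest.approx(0.0, abs=1e-9)

    def test_noise_free_migrant_recovers_parameters_within_one_percent(
            self, noise_free_trajectories):
        spec, traj, _ = noise_free_trajectories["migrant"]
        s = mc.compute_nsd(make_animal_year(traj), true_origin_fix(traj))
        f = mc.fit_model(s, "migrant")
        assert f.converged
        assert f.params.delta == pytest.approx(2500.0, rel=0.01)
        assert f.params.theta == pytest.approx(spec.departure_day, rel=0.01)
        assert f.params.phi1 == pytest.approx(spec.transition_days, rel=0.01)
        assert f.params.rho == pytest.approx(spec.residency_days, rel=0.01)

    def test_aic_uses_gaussian_nls_form(self):
        t = np.arange(365.0)
        f = mc.fit_model(series_from(t, 4.0 * t + np.sin(t)), "nomad")
        expect = f.n * math.log(f.rss / f.n) + 2 * (f.k + 1)
        assert f.aic == pytest.approx(expect)

    def test_too_few_points_raises(self):
        with pytest.raises(ValueError):
            mc.fit_model(series_from([0.0, 1.0, 2.0], [0.0, 1.0, 2.0]), "migrant")


class TestClassify:
    def test_noise_free_resident_wins(self, noise_free_trajectories):
        _, traj, _ = noise_free_trajectories["resident"]
        s = mc.compute_nsd(make_animal_year(traj), true_origin_fix(traj))
        assert mc.classify(s, "all").best_model == "resident"

    def test_linear_series_without_nomad_candidate(self):
        t = np.arange(365.0)
        res = mc.classify(series_from(t, 4.0 * t), "no_nomad")
        assert res.best_model != "nomad"
        assert "nomad" not in res.fits

    def test_binary_subset_only_fits_migrant_and_resident(self,
                                                          noise_free_trajectories):
        _, traj, _ = noise_free_trajectories["migrant"]
        s = mc.compute_nsd(make_animal_year(traj), true_origin_fix(traj))
        res = mc.classify(s, "binary")
        assert set(res.fits) == {"migrant", "resident"}
        assert res.best_model == "migrant"

    def test_altitudinal_family_excludes_nomad_and_mixed(self):
        spec = mc.BehaviourSpec("migrant", elevation_low_m=800.0,
                                elevation_high_m=1400.0, elevation_sd_m=0.0,
                                home_sd_km=0.0)
        traj, _ = mc.simulate_year(spec, 2)
        s = mc.compute_elevation_displacement(make_animal_year(traj))
        res = mc.classify(s, "all")
        assert set(res.fits) == {"migrant", "resident", "disperser"}
        assert res.best_model == "migrant"

    def test_adding_a_candidate_never_raises_best_aic(self):
        rng = np.random.default_rng(4)
        for cat in ("migrant", "resident", "disperser"):
            traj, _ = mc.simulate_year(
                mc.BehaviourSpec(cat, home_sd_km=5.0), rng)
            s = mc.compute_nsd(make_animal_year(traj))
            aic_sub = min(f.aic for f in mc.classify(s, "no_nomad").fits.values()
                          if f.converged)
            aic_all = min(f.aic for f in mc.classify(s, "all").fits.values()
                          if f.converged)
            assert aic_all <= aic_sub + 1e-9

    def test_parsimony_band_prefers_fewest_parameters(self):
        fits = {
            "resident": mc.MovementModelFit("resident", mc.ModelParams(gamma=1.0),
                                            1.0, 100, 1, 101.5, True),
            "disperser": mc.MovementModelFit("disperser", mc.ModelParams(),
                                             1.0, 100, 4, 100.0, True),
        }
        assert select_best(fits, parsimony_margin=2.0) == "resident"
        assert select_best(fits, parsimony_margin=0.0) == "disperser"


class TestSelectStart:
    def test_single_candidate_returned(self):
        traj, _ = mc.simulate_year(mc.BehaviourSpec("resident"), 1)
        sels = mc.select_start(traj, [(6, 1)], rnsd=False)
        assert len(sels) == 1
        assert sels[0].origin is traj.fixes[0]

    def test_rnsd_scan_keeps_pre_departure_origin(self, noise_free_trajectories):
        _, traj, _ = noise_free_trajectories["migrant"]
        sels = mc.select_start(traj, [(6, 1)], rnsd=True)
        origin = sels[0].origin
        assert (origin.timestamp - traj.fixes[0].timestamp).days < 30
        s = mc.compute_nsd(make_animal_year(traj), origin)
        assert s.value[0] == 0.0  # NSD is anchored at the chosen origin fix

    def test_two_anchors_give_two_independent_starts(self):
        traj, _ = mc.simulate_year(mc.BehaviourSpec("resident"), 1)
        sels = mc.select_start(traj, [(6, 1), (7, 1)], rnsd=False)
        assert len(sels) == 2
        assert sels[0].origin.timestamp < sels[1].origin.timestamp

    def test_anchor_without_nearby_fix_skipped(self):
        traj, _ = mc.simulate_year(mc.BehaviourSpec("resident"), 1)
        summer_only = mc.Trajectory(traj.animal_id, traj.fixes[:100])  # Jun-Sep
        log = mc.RejectLog()
        sels = mc.select_start(summer_only, [(3, 1)], rnsd=False, log=log)
        assert sels == [] and log.n == 1


class TestMigrationDistance:
    def test_square_root_of_delta(self):
        f = mc.MovementModelFit("migrant", mc.ModelParams(delta=2500.0),
                                0.0, 365, 5, 0.0, True)
        assert mc.migration_distance(f) == 50.0
        f.params.delta = 1.0
        assert mc.migration_distance(f) == 1.0

    def test_rejects_non_migratory_or_altitudinal_fits(self):
        res = mc.MovementModelFit("resident", mc.ModelParams(gamma=1.0),
                                  0.0, 365, 1, 0.0, True)
        with pytest.raises(ValueError):
            mc.migration_distance(res)
        alt = mc.MovementModelFit("migrant", mc.ModelParams(delta=600.0),
                                  0.0, 365, 6, 0.0, True, mode="altitudinal")
        with pytest.raises(ValueError):
            mc.migration_distance(alt)
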