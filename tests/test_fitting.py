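"""The five-step fitting procedure: step operations and round trips."""
import math
import warnings

import numpy as np
import pytest

import actoflow as af
from actoflow.fitting import (
    FitConfig,
    FitError,
    ObservedProfile,
    estimate_sigma,
    fit_adhesion_ratio,
    fit_force_scale,
    fit_viscosity_ratio,
    locate_convergence_zone,
    measure_side_speeds,
    smooth_derivative,
)


def obs(x, v, **kw):
    return ObservedProfile(positions=np.asarray(x, float),
                           velocities=np.asarray(v, float), **kw)


class TestSmoothDerivative:
    def test_exact_for_linear(self):
        x = np.linspace(0.0, 10.0, 101)
        p = obs(x, 3.0 + 2.0 * x)
        np.testing.assert_allclose(smooth_derivative(p, 1, 7), 2.0, atol=1e-10)
        np.testing.assert_allclose(smooth_derivative(p, 2, 7), 0.0, atol=1e-10)

    def test_exact_for_quadratic(self):
        x = np.linspace(-1.0, 1.0, 101)
        p = obs(x, x ** 2)
        np.testing.assert_allclose(smooth_derivative(p, 2, 7), 2.0, atol=1e-9)

    def test_matches_centered_differences_on_model_profile(self, symmetric_profile):
        p = obs(symmetric_profile.positions, symmetric_profile.velocities)
        d1 = smooth_derivative(p, 1, 7)
        g = np.gradient(p.velocities, p.positions)
        inner = slice(50, -50)
        assert np.max(np.abs(d1[inner] - g[inner])) <= 0.01 * np.max(np.abs(g))

    def test_nonuniform_grid_local_fit(self):
        x = np.sort(np.concatenate([np.linspace(0, 5, 40),
                                    np.linspace(5.05, 10, 30)]))
        p = obs(x, 1.0 + 4.0 * x)
        np.testing.assert_allclose(smooth_derivative(p, 1, 7), 4.0, atol=1e-8)

    @pytest.mark.parametrize("window", [4, 3, 6])
    def test_bad_window_rejected(self, window):
        p = obs(np.linspace(0, 1, 20), np.zeros(20))
        with pytest.raises(ValueError):
            smooth_derivative(p, 1, window)


class TestLocateConvergenceZone:
    def test_tanh_inflection(self):
        x = np.linspace(0.0, 20.0, 401)
        p = obs(x, -np.tanh(x - 10.0))
        assert locate_convergence_zone(p) == pytest.approx(10.0, abs=x[1] - x[0])

    def test_constant_profile_rejected(self):
        p = obs(np.linspace(0, 20, 100), np.full(100, 1.7))
        with pytest.raises(FitError, match="convergence zone"):
            locate_convergence_zone(p)

    @pytest.mark.parametrize("name, tol_sigmas", [
        ("cytokinesis", 0.02),
        ("neuronal_migration", 0.02),
        ("axon_outgrowth", 0.02),
        ("amoeboid_migration", 0.05),   # wide sigma: max-gradient sits slightly left of x_CZ
    ])
    def test_recovers_generating_cz(self, preset_profiles, name, tol_sigmas):
        preset, prof = preset_profiles[name]
        found = locate_convergence_zone(obs(prof.positions, prof.velocities))
        assert abs(found - preset.x_cz) <= tol_sigmas * preset.sigma


class TestEstimateSigma:
    def test_small_lambda_reference(self, symmetric_profile):
        p = obs(symmetric_profile.positions, symmetric_profile.velocities)
        xcz = locate_convergence_zone(p)
        assert estimate_sigma(p, xcz) == pytest.approx(1.0, rel=0.30)

    def test_rescaling_positions_rescales_sigma(self, symmetric_profile):
        p = obs(symmetric_profile.positions, symmetric_profile.velocities)
        s1 = estimate_sigma(p, 10.0)
        c = 2.5
        p2 = obs(c * symmetric_profile.positions, symmetric_profile.velocities)
        s2 = estimate_sigma(p2, c * 10.0)
        assert s2 == pytest.approx(c * s1, rel=1e-6)

    def test_symmetric_extrema_equidistant(self, symmetric_profile):
        p = obs(symmetric_profile.positions, symmetric_profile.velocities)
        d2 = smooth_derivative(p, 2, 7)
        x = p.positions
        icz = np.argmin(np.abs(x - 10.0))
        left = np.abs(d2[:icz - 3])
        right = np.abs(d2[icz + 4:])
        xl = x[np.argmax(left)]
        xr = x[icz + 4 + np.argmax(right)]
        assert (10.0 - xl) == pytest.approx(xr - 10.0, abs=2 * (x[1] - x[0]))

    def test_missing_extremum_raises(self):
        x = np.linspace(0, 20, 100)
        p = obs(x, x ** 2)  # constant v'': no interior |v''| extremum
        with pytest.raises(FitError, match="extremum"):
            estimate_sigma(p, 10.0)


class TestSideSpeeds:
    def test_symmetric_opposite(self, symmetric_profile):
        p = obs(symmetric_profile.positions, symmetric_profile.velocities)
        left, right = measure_side_speeds(p, 10.0, 1.0)
        assert left == pytest.approx(-right, rel=0.01)
        assert left > 0

    def test_zero_profile(self):
        p = obs(np.linspace(0, 20, 100), np.zeros(100))
        assert measure_side_speeds(p, 10.0, 1.0) == (0.0, 0.0)

    def test_empty_window_suggests_smaller_margin(self):
        p = obs(np.linspace(0, 20, 100), np.zeros(100))
        with pytest.raises(FitError, match="margin"):
            measure_side_speeds(p, 19.5, 2.0)  # right window empty at 3 sigma

    def test_amoeboid_left_dominates(self, preset_profiles):
        preset, prof = preset_profiles["amoeboid_migration"]
        p = obs(prof.positions, prof.velocities)
        left, right = measure_side_speeds(p, preset.x_cz, preset.sigma,
                                          FitConfig(margin=2.0))
        assert abs(left) / abs(right) > 10.0


class TestStepOperations:
    def test_adhesion_ratio_symmetric_fixed_point(self, preset_profiles):
        preset, prof = preset_profiles["cytokinesis"]
        params = preset.to_model_params()
        xi = fit_adhesion_ratio(obs(prof.positions, prof.velocities), params)
        assert xi == pytest.approx(1.0, rel=1e-3)

    def test_adhesion_ratio_mesenchymal_recovery(self, preset_profiles):
        preset, prof = preset_profiles["mesenchymal_migration"]
        params = preset.to_model_params()
        xi = fit_adhesion_ratio(obs(prof.positions, prof.velocities), params)
        assert xi == pytest.approx(6.5, rel=0.20)

    def test_side_ratio_monotone_in_adhesion_ratio(self, preset_profiles):
        """The model right/left speed ratio decreases monotonically with
        xi_R/xi_L (scan oracle), so the root search is well posed."""
        preset, prof = preset_profiles["mesenchymal_migration"]
        from actoflow.fitting import _Workspace
        ws = _Workspace(obs(prof.positions, prof.velocities),
                        preset.x_cz, preset.sigma, FitConfig())
        ratios = []
        for t in np.linspace(-2, 2, 20):
            l, r = ws.sides(10.0 ** t, preset.mu_ratio)
            ratios.append(abs(r) / abs(l))
        assert np.all(np.diff(ratios) < 0)

    def test_force_scale_fixed_point_and_linearity(self, preset_profiles):
        preset, prof = preset_profiles["axon_outgrowth"]
        params = preset.to_model_params()
        p1 = obs(prof.positions, prof.velocities)
        f1 = fit_force_scale(p1, params)
        assert f1 == pytest.approx(preset.force_scale, rel=0.10)
        p2 = obs(prof.positions, 2.0 * prof.velocities)
        assert fit_force_scale(p2, params) == pytest.approx(2.0 * f1, rel=1e-9)

    def test_viscosity_mesenchymal_recovery(self, preset_profiles):
        preset, prof = preset_profiles["mesenchymal_migration"]
        params = preset.to_model_params()
        mu, flat, _ = fit_viscosity_ratio(obs(prof.positions, prof.velocities),
                                          params)
        assert mu == pytest.approx(5.0e2, rel=0.30)
        assert not flat

    def test_viscosity_neuronal_flat_flag(self, preset_profiles):
        preset, prof = preset_profiles["neuronal_migration"]
        params = preset.to_model_params()
        with pytest.warns(RuntimeWarning, match="flat"):
            mu, flat, lower = fit_viscosity_ratio(
                obs(prof.positions, prof.velocities), params)
        assert flat
        assert lower is not None and lower < preset.mu_ratio


class TestFitProfile:
    @pytest.mark.parametrize("name", ["cytokinesis", "mesenchymal_migration"])
    def test_noiseless_round_trip_rms(self, preset_profiles, name):
        _, prof = preset_profiles[name]
        res = af.fit_profile(prof)
        assert res.rms_residual < 0.01 * np.max(np.abs(prof.velocities))
        assert res.converged

    def test_symmetric_input_recovers_symmetry(self, preset_profiles):
        preset, prof = preset_profiles["cytokinesis"]
        res = af.fit_profile(prof)
        assert res.xi_ratio == pytest.approx(1.0, rel=0.20)
        params = res.to_model_params(L=preset.L)
        summ = af.flow_summary(af.solve_flow(params), params)
        peak = np.max(np.abs(prof.velocities))
        assert abs(summ.com_velocity) < 0.05 * peak

    def test_position_shift_invariance(self, preset_profiles):
        _, prof = preset_profiles["mesenchymal_migration"]
        res1 = af.fit_profile(prof)
        shifted = ObservedProfile(prof.positions + 5.0, prof.velocities)
        res2 = af.fit_profile(shifted)
        assert res2.x_cz - res1.x_cz == pytest.approx(5.0, abs=1e-6)
        for attr in ("sigma", "xi_ratio", "force_scale", "mu_ratio"):
            assert getattr(res2, attr) == pytest.approx(
                getattr(res1, attr), rel=1e-3)

    def test_result_invariants(self, preset_profiles):
        _, prof = preset_profiles["axon_outgrowth"]
        res = af.fit_profile(prof)
        assert res.lam == pytest.approx(2.0 * res.mu_ratio / res.sigma ** 2)
        assert res.rms_residual >= 0
        assert all(getattr(res, a) > 0 for a in
                   ("sigma", "xi_ratio", "force_scale", "mu_ratio"))
        # the recorded per-pass RMS never ends above its starting value
        log = res.diagnostics["rms_per_pass"]
        assert res.rms_residual <= log[0] + 1e-12


class TestGoodnessOfFit:
    @staticmethod
    def result_from(preset):
        return af.FitResult(
            x_cz=preset.x_cz, sigma=preset.sigma, xi_ratio=preset.xi_ratio,
            force_scale=preset.force_scale, mu_ratio=preset.mu_ratio,
            rms_residual=0.0, n_iterations=1, converged=True)

    def test_exact_model_scores_zero(self, preset_profiles):
        preset, prof = preset_profiles["cytokinesis"]
        rms, nrms = af.goodness_of_fit(prof, self.result_from(preset))
        assert nrms < 1e-6

    def test_constant_offset_equals_rms(self, preset_profiles):
        preset, prof = preset_profiles["cytokinesis"]
        c = 0.37 * np.max(np.abs(prof.velocities))
        shifted = ObservedProfile(prof.positions, prof.velocities + c)
        rms, _ = af.goodness_of_fit(shifted, self.result_from(preset))
        assert rms == pytest.approx(c, rel=1e-4)

    def test_noise_floor(self, preset_profiles):
        preset, _ = preset_profiles["cytokinesis"]
        noisy = af.generate_profile(preset, af.NoiseSpec(sd=0.05, seed=42))
        s = 0.05 * np.max(np.abs(af.generate_profile(preset).velocities))
        rms, _ = af.goodness_of_fit(noisy, self.result_from(preset))
        assert rms == pytest.approx(s, rel=0.30)


class TestObservedProfileType:
    def test_minimum_length(self):
        with pytest.raises(ValueError, match="15"):
            obs(np.linspace(0, 1, 10), np.zeros(10))

    def test_monotone_positions(self):
        x = np.linspace(0, 1, 20)
        x[5] = x[4]
        with pytest.raises(ValueError, match="increasing"):
            obs(x, np.zeros(20))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            FitConfig(window=6)
        with pytest.raises(ValueError):
            FitConfig(tol=0.0)
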