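"""Curve pipeline: calibration, baseline, contact point, modulus and QC."""

import warnings
from dataclasses import replace

import numpy as np
import pytest

from elastimap import (
    Cantilever,
    ElasticHalfSpace,
    ForceCurve,
    Indenter,
    calibrate,
    compute_indentation,
    find_contact_point,
    fit_baseline,
    fit_modulus,
    fit_stiffness,
    hertz_stiffness,
    process_curve,
    qc_setpoints,
    simulate_curve,
)
from elastimap.processing import (
    ContactNotFoundError,
    FitResult,
    IndentationCurve,
    InsufficientDataError,
    QCVerdict,
    _subtract_baseline,
)
from elastimap.stats import correlate_K_k
from elastimap.synthetic import QUIET, NoiseModel


def _flat_curve(n=2000, k_c=0.09, deflection=None, setpoint=30e-9):
    t = np.linspace(0, 1.0, n)
    z = 20e-6 * t
    d = np.zeros(n) if deflection is None else deflection
    return ForceCurve(time=t, height=z, deflection=d, extend_end=n,
                      cantilever=Cantilever(k_c), bead_radius=44.65e-6,
                      setpoint_force=setpoint, setpoint_speed=20e-6)


class TestCalibrate:
    def test_force_is_spring_constant_times_deflection(self):
        c = _flat_curve(deflection=np.full(2000, 100e-9), k_c=0.3)
        cal = calibrate(c)
        np.testing.assert_allclose(cal.force, 30e-9)

    def test_zero_deflection_gives_zero_force(self):
        cal = calibrate(_flat_curve())
        assert np.all(cal.force == 0.0)

    def test_idempotent_on_precalibrated(self):
        c = _flat_curve()
        pre = replace(calibrate(c), deflection=None)
        assert calibrate(pre) is pre

    def test_conflicting_cantilever_raises(self):
        pre = replace(calibrate(_flat_curve(k_c=0.09)), deflection=None)
        with pytest.raises(ValueError, match="pre-calibrated"):
            calibrate(pre, Cantilever(0.5))

    def test_setpoint_reached_within_noise(self, noisy_curve):
        cal = calibrate(noisy_curve)
        sd_equiv = 0.01 * noisy_curve.setpoint_force
        achieved = np.max(cal.force)
        assert abs(achieved - noisy_curve.setpoint_force) < 6 * sd_equiv


class TestBaseline:
    def test_flat_zero_baseline(self):
        offset, tilt = fit_baseline(calibrate(_flat_curve()))
        assert offset == pytest.approx(0.0, abs=1e-18)
        assert tilt == pytest.approx(0.0, abs=1e-12)

    def test_recovers_known_offset_and_tilt(self, soft_cantilever):
        noise = NoiseModel(noise_fraction=0.0005, baseline_offset_range=0.5e-9,
                           baseline_tilt_range=1e-5, seed=11)
        curve = simulate_curve(250.0, cantilever=soft_cantilever, noise=noise)
        truth_off = curve.ground_truth["baseline_offset"]
        truth_tilt = curve.ground_truth["baseline_tilt"]
        offset, tilt = fit_baseline(calibrate(curve),
                                    z_limit=curve.ground_truth["z_c"])
        assert offset == pytest.approx(truth_off, abs=0.2e-9)
        assert tilt == pytest.approx(truth_tilt, abs=0.1e-5)

    def test_insufficient_precontact_window_raises(self):
        c = calibrate(_flat_curve(n=2000))
        with pytest.raises(InsufficientDataError):
            fit_baseline(c, z_limit=c.height[3])


class TestContactPoint:
    def test_noise_free_recovery_below_grid_pitch(self, quiet_curve, indenter):
        cal = calibrate(quiet_curve)
        z_c, fit = find_contact_point(cal, indenter, "hertz")
        assert abs(z_c - quiet_curve.ground_truth["z_c"]) < 0.1e-6
        assert fit.K == pytest.approx(250.0, rel=1e-3)

    def test_pure_baseline_curve_raises(self, indenter):
        rng = np.random.default_rng(0)
        c = calibrate(_flat_curve(deflection=rng.normal(0, 1e-9, 2000)))
        with pytest.raises(ContactNotFoundError):
            find_contact_point(c, indenter, "hertz")

    def test_noisy_recovery_monte_carlo(self, soft_cantilever, indenter):
        # 1% deflection noise: z_c within 0.5 um of truth in >= 95% of runs
        hits = 0
        n_rep = 40
        for seed in range(n_rep):
            curve = simulate_curve(250.0, cantilever=soft_cantilever,
                                   noise=NoiseModel(seed=100 + seed))
            fit, _, qc = process_curve(curve)
            if qc.keep and abs(fit.contact_point - curve.ground_truth["z_c"]) < 0.5e-6:
                hits += 1
        assert hits >= 0.95 * n_rep


class TestIndentation:
    def test_rigid_sample_gives_zero_indentation(self):
        n = 2000
        t = np.linspace(0, 1, n)
        z = 20e-6 * t
        z_c = 10e-6
        d = np.clip(z - z_c, 0, None)  # deflection rises 1:1 past contact
        c = ForceCurve(time=t, height=z, deflection=d, extend_end=n,
                       cantilever=Cantilever(0.09), bead_radius=44.65e-6)
        ind = compute_indentation(calibrate(c), z_c)
        np.testing.assert_allclose(ind.indentation[z > z_c], 0.0, atol=1e-18)

    def test_free_cantilever_indentation_equals_travel(self):
        c = calibrate(_flat_curve())
        z_c = 5e-6
        ind = compute_indentation(c, z_c)
        np.testing.assert_allclose(ind.indentation, c.height[: c.extend_end] - z_c)

    def test_out_of_range_contact_point_raises(self):
        c = calibrate(_flat_curve())
        with pytest.raises(ValueError, match="outside extend z range"):
            compute_indentation(c, 1.0)

    def test_generator_max_depth_matches_truth(self, quiet_curve):
        cal = calibrate(quiet_curve)
        ind = compute_indentation(cal, quiet_curve.ground_truth["z_c"])
        assert ind.delta_max == pytest.approx(
            quiet_curve.ground_truth["delta_max"], rel=1e-6)


class TestFitModulus:
    @pytest.mark.parametrize("model", ["hertz", "sneddon"])
    def test_noise_free_recovery(self, model, soft_cantilever, indenter):
        from elastimap import sneddon_force

        if model == "hertz":
            cant, force = soft_cantilever, 30e-9
        else:
            cant = Cantilever(2.0)
            # setpoint chosen so the true depth is half the bead radius
            force = float(sneddon_force(ElasticHalfSpace(250.0), indenter,
                                        0.5 * indenter.radius))
        curve = simulate_curve(250.0, cantilever=cant, setpoint_force=force,
                               noise=QUIET, model=model)
        cal = calibrate(curve)
        ind = compute_indentation(cal, curve.ground_truth["z_c"])
        fit = fit_modulus(ind, indenter, model)
        assert fit.ok
        assert fit.K == pytest.approx(250.0, rel=1e-3)

    def test_model_mismatch_biases_hertz_at_depth(self, indenter):
        # deep sphere indentation fitted as a paraboloid underestimates K
        curve = simulate_curve(1000.0, cantilever=Cantilever(2.0),
                               setpoint_force=1200e-9, noise=QUIET, model="sneddon")
        cal = calibrate(curve)
        ind = compute_indentation(cal, curve.ground_truth["z_c"])
        fit_s = fit_modulus(ind, indenter, "sneddon")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit_h = fit_modulus(ind, indenter, "hertz")
        assert fit_s.K == pytest.approx(1000.0, rel=1e-3)
        assert abs(fit_h.K - 1000.0) / 1000.0 > 0.02

    def test_hertz_regime_threshold(self, quiet_curve, indenter):
        cal = calibrate(quiet_curve)
        ind = compute_indentation(cal, quiet_curve.ground_truth["z_c"])
        fit = fit_modulus(ind, indenter, "hertz")
        # 14 um on a 44.65 um bead is just inside the delta/R < 1/3 regime
        assert 14e-6 / 44.65e-6 < 1 / 3
        assert fit.hertz_regime == (fit.delta_max_over_R < 1 / 3)

    def test_failure_verdict_not_exception(self, indenter):
        ind = IndentationCurve(indentation=np.linspace(0, 5e-6, 100),
                               force=-np.linspace(0, 30e-9, 100),
                               contact_point=0.0)
        fit = fit_modulus(ind, indenter, "hertz")
        assert not fit.ok
        assert fit.failure_reason == "fit_failure"
        assert np.isnan(fit.K)


class TestFitStiffness:
    def test_exact_linear_slope(self):
        delta = np.linspace(0, 10e-6, 500)
        ind = IndentationCurve(indentation=delta, force=0.01 * delta,
                               contact_point=0.0)
        res = fit_stiffness(ind)
        assert res.k == pytest.approx(0.01, rel=1e-9)
        assert res.n_points >= 5

    def test_matches_analytic_tangent_on_hertz_curve(self, quiet_curve, indenter):
        cal = calibrate(quiet_curve)
        ind = compute_indentation(cal, quiet_curve.ground_truth["z_c"])
        res = fit_stiffness(ind)
        tangent = hertz_stiffness(ElasticHalfSpace(250.0), indenter, ind.delta_max)
        assert res.k == pytest.approx(tangent, rel=0.03)

    def test_too_few_samples_raises(self):
        delta = np.linspace(0, 10e-6, 10)
        ind = IndentationCurve(indentation=delta, force=0.01 * delta ** 2 / 1e-6,
                               contact_point=0.0)
        with pytest.raises(InsufficientDataError):
            fit_stiffness(ind, window=(0.999, 1.0))


class TestQC:
    def _fit_ok(self):
        return FitResult(K=200.0, model="hertz", contact_point=5e-6, delta_max=5e-6,
                         delta_max_over_R=0.1, residual_rms=0.0, n_points_fit=100,
                         hertz_regime=True)

    def _curve_with_peak(self, peak, setpoint=30e-9):
        n = 2000
        t = np.linspace(0, 1, n)
        z = 20e-6 * t
        f = np.linspace(0, peak, n)
        return ForceCurve(time=t, height=z, deflection=None, force=f, extend_end=n,
                          cantilever=Cantilever(0.09), bead_radius=44.65e-6,
                          setpoint_force=setpoint, setpoint_speed=20e-6)

    def test_within_ten_percent_keeps(self):
        verdict = qc_setpoints(self._curve_with_peak(32e-9), self._fit_ok())
        assert verdict.keep
        assert verdict.achieved_force == pytest.approx(32e-9)

    def test_beyond_ten_percent_excludes(self):
        verdict = qc_setpoints(self._curve_with_peak(26e-9), self._fit_ok())
        assert not verdict.keep
        assert verdict.reasons == ["force_deviation"]

    def test_fit_failure_always_excludes(self):
        verdict = qc_setpoints(self._curve_with_peak(30e-9),
                               FitResult.failure("hertz", "fit_failure"))
        assert not verdict.keep
        assert "fit_failure" in verdict.reasons

    def test_verdict_invariant(self):
        with pytest.raises(ValueError):
            QCVerdict(keep=True, reasons=["force_deviation"])


class TestPipelineProperties:
    def test_translation_invariance(self, quiet_curve):
        fit1, _, _ = process_curve(quiet_curve)
        shifted = replace(quiet_curve, height=quiet_curve.height + 13e-6)
        fit2, _, _ = process_curve(shifted)
        assert fit2.contact_point - fit1.contact_point == pytest.approx(13e-6, abs=1e-9)
        assert fit2.K == pytest.approx(fit1.K, rel=1e-6)

    def test_baseline_invariance(self, quiet_curve, soft_cantilever):
        fit0, _, _ = process_curve(quiet_curve)
        k_c = soft_cantilever.spring_constant
        tilted = replace(
            quiet_curve,
            deflection=quiet_curve.deflection
            + (0.5e-9 + 1e-5 * quiet_curve.height) / k_c,
        )
        fit1, _, qc = process_curve(tilted)
        assert qc.keep
        assert abs(fit1.K - fit0.K) / fit0.K < 0.02

    def test_K_k_correlation_across_population(self, soft_cantilever):
        # fitted K and fitted k must co-vary strongly over a varied population
        Ks, ks = [], []
        for i, K_true in enumerate(np.geomspace(60, 1200, 15)):
            curve = simulate_curve(float(K_true), cantilever=soft_cantilever,
                                   noise=NoiseModel(seed=300 + i))
            fit, stiff, qc = process_curve(curve)
            if qc.keep and stiff is not None:
                Ks.append(fit.K)
                ks.append(stiff.k)
        assert len(Ks) >= 12
        r, _ = correlate_K_k(Ks, ks)
        assert r > 0.9
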