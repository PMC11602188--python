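import numpy as np
import pytest

from stickreach import (
    LearnerParams,
    LearnerState,
    PlaneState,
    fit_params,
    linear_relation,
    prediction_errors,
    simulate_adaptation,
    update_state,
)
from stickreach.learner import _predict_series
from stickreach.relation import BaselineRelation
from stickreach.simulate import make_protocol

NOISELESS = dict(motor_noise_tmd=0.0, motor_noise_sta=0.0)


class TestPredictionErrors:
    def test_on_relation_unperturbed_gives_zero(self, relation02):
        vis = PlaneState(5.0, 1.0, "visual")  # on the slope-0.2 relation
        assert prediction_errors(vis, 5.0, relation02) == (0.0, 0.0)

    def test_tilt_perturbation_first_trial(self, relation02):
        """Seen (0, +6) while expecting tilt 0 at TMD 0: pure tilt error -6."""
        assert prediction_errors(PlaneState(0.0, 6.0, "visual"), 0.0, relation02) == (0.0, -6.0)

    def test_fully_compensated_tip_rotation_leaves_tilt_error(self, relation02):
        """After full compensation the seen tilt is g(-30) at seen TMD 0."""
        g_m30 = relation02.evaluate(-30.0)
        e = prediction_errors(PlaneState(0.0, g_m30, "visual"), 0.0, relation02)
        assert e[0] == 0.0
        assert e[1] == pytest.approx(-g_m30)
        assert e[1] != 0.0

    def test_rejects_physical_frame(self, relation02):
        with pytest.raises(ValueError, match="frame"):
            prediction_errors(PlaneState(0.0, 0.0, "physical"), 0.0, relation02)


class TestUpdateState:
    def test_zero_error_zero_decay_is_fixed_point(self, relation02):
        state = LearnerState(intent=PlaneState(-5.0, -1.0, "physical"))
        params = LearnerParams(retention_loss=0.0, **NOISELESS)
        new = update_state(state, (0.0, 0.0), params, relation02)
        assert (new.intent.tmd, new.intent.sta) == (-5.0, -1.0)

    def test_tilt_error_moves_both_dimensions_down_the_relation(self, relation02):
        """A CW tilt error with a rising relation shifts TMD and STA together CW."""
        state = LearnerState(intent=PlaneState(0.0, 0.0, "physical"))
        params = LearnerParams(eta_tmd=0.1, eta_sta=0.1, **NOISELESS)
        new = update_state(state, (0.0, -6.0), params, relation02)
        assert new.intent.tmd < 0
        assert new.intent.sta < 0

    def test_flat_relation_ignores_tilt_error(self):
        flat = linear_relation(0.0)
        state = LearnerState(intent=PlaneState(0.0, 0.0, "physical"))
        params = LearnerParams(eta_tmd=0.1, eta_sta=0.5, **NOISELESS)
        new = update_state(state, (0.0, -6.0), params, flat)
        assert (new.intent.tmd, new.intent.sta) == (0.0, 0.0)

    def test_update_is_parallel_to_relation_tangent(self, relation02, rng):
        params = LearnerParams(eta_tmd=0.13, eta_sta=0.21, **NOISELESS)
        for _ in range(50):
            intent = PlaneState(rng.uniform(-30, 30), rng.uniform(-6, 6), "physical")
            state = LearnerState(intent=intent)
            errs = (rng.uniform(-10, 10), rng.uniform(-10, 10))
            new = update_state(state, errs, params, relation02)
            delta = np.array([new.intent.tmd - intent.tmd, new.intent.sta - intent.sta])
            s = relation02.slope(intent.tmd)
            assert abs(delta[0] * s - delta[1]) < 1e-9

    def test_retention_decays_toward_baseline_intent(self, relation02):
        base = PlaneState(0.0, 0.0, "physical")
        state = LearnerState(intent=PlaneState(-10.0, -2.0, "physical"))
        params = LearnerParams(retention_loss=0.1, **NOISELESS)
        new = update_state(state, (0.0, 0.0), params, relation02, baseline_intent=base)
        assert new.intent.tmd == pytest.approx(-9.0)
        assert new.intent.sta == pytest.approx(-1.8)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            LearnerParams(eta_tmd=1.5)
        with pytest.raises(ValueError):
            LearnerParams(retention_loss=0.3)
        with pytest.raises(ValueError):
            LearnerParams(motor_noise_tmd=-1.0)


class TestSimulateAdaptation:
    def test_all_off_noise_free_is_constant(self, relation02):
        _, spec = make_protocol("E1A")
        from stickreach import PerturbationSpec

        off = PerturbationSpec()
        sim = simulate_adaptation(50, LearnerParams(**NOISELESS), relation02, off)
        assert np.all(sim["exec_tmd_deg"] == 0.0)
        assert np.all(sim["exec_sta_deg"] == 0.0)

    def test_gradual_tip_rotation_converges_without_tilt_learning(self, relation02):
        """Pure task-error learning fully counter-rotates: TMD -> -30 deg."""
        _, spec = make_protocol("E1A")
        params = LearnerParams(eta_tmd=0.2, eta_sta=0.0, **NOISELESS)
        sim = simulate_adaptation(240, params, relation02, spec)
        assert sim["exec_tmd_deg"].iloc[-1] == pytest.approx(-30.0, abs=1e-3)

    def test_tilt_learning_creates_residual_error(self, relation02):
        """With eta_sta > 0 the tilt correction de-adapts TMD: |TMD*| < 30."""
        _, spec = make_protocol("E1A")
        params = LearnerParams(eta_tmd=0.2, eta_sta=0.2, **NOISELESS)
        sim = simulate_adaptation(240, params, relation02, spec)
        final = sim["exec_tmd_deg"].iloc[-1]
        assert -30.0 < final < 0.0
        # steady state of the fixed-point equation eta_m(m+30) = s^2 eta_a 30
        s = 0.2
        expected = -30.0 + 30.0 * s * s * params.eta_sta / params.eta_tmd
        assert final == pytest.approx(expected, abs=1e-3)

    def test_reproducible_given_seed(self, relation02):
        _, spec = make_protocol("E2CCW")
        params = LearnerParams(seed=42)
        a = simulate_adaptation(60, params, relation02, spec)
        b = simulate_adaptation(60, params, relation02, spec)
        assert a.equals(b)

    def test_fast_path_matches_reference_simulation(self, relation02):
        """Array fast path and the object-level simulation agree exactly."""
        _, spec = make_protocol("E3CW")
        params = LearnerParams(eta_tmd=0.12, eta_sta=0.07, retention_loss=0.02, **NOISELESS)
        sim = simulate_adaptation(120, params, relation02, spec)
        m, a = _predict_series(120, 0.12, 0.07, 0.02, relation02, spec, 0.0)
        np.testing.assert_allclose(sim["exec_tmd_deg"], m, atol=1e-12)
        np.testing.assert_allclose(sim["exec_sta_deg"], a, atol=1e-12)

    def test_fast_path_matches_on_piecewise_relation(self):
        rel = BaselineRelation(knots=np.array([[-40.0, -7.0], [0.0, 0.0], [40.0, 9.0]]))
        _, spec = make_protocol("E1A")
        params = LearnerParams(eta_tmd=0.15, eta_sta=0.1, **NOISELESS)
        sim = simulate_adaptation(100, params, rel, spec)
        m, a = _predict_series(100, 0.15, 0.1, 0.0, rel, spec, 0.0)
        np.testing.assert_allclose(sim["exec_tmd_deg"], m, atol=1e-12)
        np.testing.assert_allclose(sim["exec_sta_deg"], a, atol=1e-12)


class TestFitParams:
    def test_noiseless_self_consistency(self, relation02):
        _, spec = make_protocol("E1A")
        truth = LearnerParams(eta_tmd=0.1, eta_sta=0.1, retention_loss=0.0, **NOISELESS)
        sim = simulate_adaptation(240, truth, relation02, spec)
        fit = fit_params(sim["exec_tmd_deg"], sim["exec_sta_deg"], spec, relation02)
        assert fit.params.eta_tmd == pytest.approx(0.1)
        assert fit.params.eta_sta == pytest.approx(0.1)
        assert fit.params.retention_loss == pytest.approx(0.0)
        assert fit.sse < 1e-12
        assert not fit.flat_objective

    def test_zero_tilt_rate_truth_recovered(self, relation02):
        _, spec = make_protocol("E1A")
        truth = LearnerParams(eta_tmd=0.15, eta_sta=0.0, **NOISELESS)
        sim = simulate_adaptation(240, truth, relation02, spec)
        fit = fit_params(sim["exec_tmd_deg"], sim["exec_sta_deg"], spec, relation02)
        assert fit.params.eta_sta == 0.0
        assert fit.params.eta_tmd == pytest.approx(0.15)

    def test_flat_objective_reported(self, relation02):
        """Without perturbation and starting at baseline, all params are equivalent."""
        from stickreach import PerturbationSpec

        off = PerturbationSpec()
        n = 50
        fit = fit_params(np.zeros(n), np.zeros(n), off, relation02)
        assert fit.flat_objective
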