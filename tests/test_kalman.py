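import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fruittrack.io import Detection
from fruittrack.kalman import MotionModel, Track, init_track, nearest_stable_speed


@pytest.fixture
def model():
    return MotionModel()


def make_track(state, P=None, update_count=1, id=0):
    return Track(id=id, state=np.asarray(state, float),
                 P=np.eye(4) if P is None else P, update_count=update_count)


class TestMotionModel:
    def test_matrices_match_constant_velocity_form(self, model):
        F = model.F
        assert np.allclose(F, [[1, 0, 1, 0], [0, 1, 0, 1], [0, 0, 1, 0], [0, 0, 0, 1]])
        assert np.allclose(model.H, [[1, 0, 0, 0], [0, 1, 0, 0]])
        assert np.allclose(model.Q, np.eye(4))
        assert np.allclose(model.R, 0.1 * np.eye(2))

    def test_two_unit_steps_equal_one_double_step(self, model):
        # F(1) @ F(1) == F(2) on the state mean
        F1, F2 = model.F, MotionModel(dt=2.0).F
        assert np.allclose(F1 @ F1, F2)


class TestInitTrack:
    def test_state_from_centroid_and_speed(self):
        d = Detection(0, 85, 180, 30, 40)  # centre (100, 200)
        t = init_track(d, (20, 0), id=0)
        assert np.allclose(t.state, [100, 200, 20, 0])
        assert t.update_count == 1
        assert t.unobserved_count == 0
        assert np.allclose(t.P, 10.0 * np.eye(4))

    def test_zero_speed_is_stationary(self, model):
        t = init_track(Detection(0, 40, 50, 20, 20), (0, 0), id=1)
        state, _ = t.predict(model)
        assert np.allclose(state[:2], t.position)


class TestPredict:
    def test_position_advances_by_velocity(self, model):
        t = make_track([100, 200, 20, 0])
        state, _ = t.predict(model)
        assert np.allclose(state, [120, 200, 20, 0])

    def test_zero_velocity_fixed_point(self, model):
        t = make_track([50, 60, 0, 0])
        state, _ = t.predict(model)
        assert np.allclose(state[:2], [50, 60])

    def test_covariance_propagation_identity_case(self, model):
        # P = I, Q = I: P' = F F^T + I; position variances become 3
        t = make_track([0, 0, 0, 0], P=np.eye(4))
        _, P = t.predict(model)
        assert np.allclose(P, model.F @ model.F.T + np.eye(4))
        assert P[0, 0] == P[1, 1] == 3.0

    def test_predict_does_not_mutate(self, model):
        t = make_track([1, 2, 3, 4])
        t.predict(model)
        assert np.allclose(t.state, [1, 2, 3, 4])
        assert t.update_count == 1 and t.unobserved_count == 0


class TestUpdate:
    def test_zero_residual_keeps_prediction(self, model):
        t = make_track([100, 200, 20, 0])
        t.update([120, 200], model, frame=1)
        assert np.allclose(t.state[:2], [120, 200])
        assert np.allclose(t.state[2:], [20, 0])
        assert t.update_count == 2 and t.unobserved_count == 0

    def test_unit_residual_gain(self):
        # engineered so the prior is exactly P' = I4: P=0, Q=I, with
        # R = 0.1 I the position gain is 1/1.1 and velocities are untouched
        model = MotionModel(q=1.0, r=0.1)
        t = make_track([100, 200, 20, 0], P=np.zeros((4, 4)))
        t.update([121, 201], model, frame=1)
        assert np.allclose(t.state[:2], [120 + 1 / 1.1, 200 + 1 / 1.1])
        assert np.allclose(t.state[2:], [20, 0])

    def test_diffuse_prior_snaps_to_measurement(self, model):
        t = make_track([0, 0, 0, 0], P=1e6 * np.eye(4))
        t.update([345.0, 678.0], model, frame=1)
        assert np.allclose(t.state[:2], [345.0, 678.0], atol=1e-3)

    def test_near_zero_measurement_noise_returns_measurement(self):
        model = MotionModel(r=1e-12)
        t = make_track([10, 10, 5, 5])
        t.update([300.0, 400.0], model, frame=1)
        assert np.allclose(t.state[:2], [300.0, 400.0], atol=1e-6)


class TestConvergence:
    def test_matched_initial_speed_predicts_exactly(self, model):
        # stream moving at the platform's nominal shift, track initialised
        # with the global default speed: the prediction is exact throughout
        v = (20.0, 0.0)
        t = init_track(Detection(0, 85, 185, 30, 30), v, id=0)  # centre (100, 200)
        errs = []
        for k in range(1, 11):
            z = np.array([100 + 20 * k, 200.0])
            state, _ = t.predict(model)
            errs.append(np.hypot(*(state[:2] - z)))
            t.update(z, model, frame=k)
        assert all(e < 1e-6 for e in errs[3:])
        assert all(a >= b - 1e-12 for a, b in zip(errs, errs[1:]))  # non-increasing

    def test_perturbed_initial_speed_decays_monotonically(self, model):
        t = init_track(Detection(0, 85, 185, 30, 30), (10.0, 5.0), id=0)
        errs = []
        for k in range(1, 13):
            z = np.array([100 + 20 * k, 200.0])
            state, _ = t.predict(model)
            errs.append(np.hypot(*(state[:2] - z)))
            t.update(z, model, frame=k)
        assert all(a > b for a, b in zip(errs, errs[1:]))
        assert errs[-1] < 1e-2

    def test_small_process_noise_velocity_converges(self):
        model = MotionModel(q=1e-9, r=0.1)
        t = init_track(Detection(0, -15, -15, 30, 30), (0.0, 0.0), id=0)
        for k in range(1, 51):
            t.update([3.0 * k, -2.0 * k], model, frame=k)
        assert np.allclose(t.velocity, [3.0, -2.0], atol=1e-3)

    @given(st.lists(st.tuples(st.floats(-500, 500), st.floats(-500, 500)),
                    min_size=1, max_size=25))
    def test_covariance_symmetric_psd_through_any_sequence(self, zs):
        model = MotionModel()
        t = init_track(Detection(0, 0.5, 0.5, 30, 30), (20, 0), id=0)
        for k, z in enumerate(zs, start=1):
            if k % 3 == 0:
                t.coast(model)
            else:
                t.update(z, model, frame=k)
            assert np.abs(t.P - t.P.T).max() < 1e-9
            assert np.linalg.eigvalsh(t.P).min() > -1e-9


class TestUnassignedHandling:
    def test_stable_track_registers_prediction(self, model):
        t = make_track([120, 200, 20, 0], update_count=5)
        t.handle_unassigned([], (20, 0), model)
        assert np.allclose(t.position, [140, 200])
        assert t.unobserved_count == 1
        assert t.update_count == 5  # no measurement happened

    def test_unstable_track_borrows_neighbour_speed(self, model):
        t = make_track([100, 100, 20, 0], update_count=2, id=0)
        near = make_track([110, 100, 18, 1], update_count=6, id=1)
        far = make_track([900, 900, -5, 3], update_count=6, id=2)
        t.handle_unassigned([near, far], (20, 0), model)
        # artificial measurement was (118, 101); posterior lands near it
        assert np.allclose(t.position, [118, 101], atol=0.5)
        assert t.unobserved_count == 1
        assert t.update_count == 2  # artificial updates never add stability

    def test_no_stable_neighbour_uses_default_speed(self, model):
        # artificial measurement is (120, 100); with P = I the prior
        # position variance is 3, so the posterior moves by 20 * 3/3.1
        t = make_track([100, 100, 0, 0], update_count=2)
        t.handle_unassigned([], (20, 0), model)
        assert np.allclose(t.position, [100 + 20 * 3 / 3.1, 100], atol=1e-9)
        assert t.unobserved_count == 1

    def test_borrow_tie_breaks_to_lower_id(self):
        a = make_track([10, 0, 1, 1], update_count=6, id=7)
        b = make_track([-10, 0, 2, 2], update_count=6, id=3)
        speed = nearest_stable_speed([0, 0], [a, b], (20, 0))
        assert speed == (2.0, 2.0)
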