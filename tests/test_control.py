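"""Inverse plant model: quadratic solve, recursion, control pipeline."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import lvcontrol as lv
from lvcontrol.control import (FLAG_CLAMPED, FLAG_LINEAR, FLAG_OK,
                               FLAG_VERTEX, QuadraticTerms)
from lvcontrol.errors import DataError, UnsolvableEventError

from conftest import random_coefficients, random_train


class TestQuadraticTerms:
    def test_first_event_terms(self, small_basis, rng):
        plant = random_coefficients(rng, small_basis)
        q = lv.quadratic_terms(plant, np.zeros(3), y_desired=0.4)
        assert q.a == plant.c2_present
        assert q.b == plant.c1_present
        assert q.c == pytest.approx(plant.c0 - 0.4)

    def test_known_amplitude_is_a_root(self, small_basis, rng):
        plant = random_coefficients(rng, small_basis)
        train = random_train(rng, n_events=12)
        y = lv.predict_output(plant, small_basis, train)
        i = 7
        v = lv.convolve_events(small_basis, train, i)
        q = lv.quadratic_terms(plant, v, y[i])
        A = train.amplitudes[i]
        assert q.a * A ** 2 + q.b * A + q.c == pytest.approx(0.0, abs=1e-12)

    def test_vanishing_quadratic_term(self, small_basis):
        plant = lv.LVCoefficients(0.1, 4e-3, 0.0, np.zeros(3),
                                  np.zeros((3, 3)), np.zeros(3))
        q = lv.quadratic_terms(plant, np.zeros(3), 0.5)
        assert q.a == 0.0
        A, flag = lv.solve_amplitude(q)
        assert flag == FLAG_LINEAR
        assert A == pytest.approx((0.5 - 0.1) / 4e-3)


class TestSolveAmplitude:
    def test_plus_branch_simple_root(self):
        A, flag = lv.solve_amplitude(QuadraticTerms(1.0, 0.0, -4.0))
        assert (A, flag) == (2.0, FLAG_OK)

    def test_negative_discriminant_vertex(self):
        A, flag = lv.solve_amplitude(QuadraticTerms(1.0, 0.0, 4.0))
        assert (A, flag) == (0.0, FLAG_VERTEX)

    def test_negative_root_clamped(self):
        # roots -1 and -3: physically meaningless, clamp to zero
        A, flag = lv.solve_amplitude(QuadraticTerms(1.0, 4.0, 3.0))
        assert (A, flag) == (0.0, FLAG_CLAMPED)

    def test_degenerate_event_unsolvable(self):
        with pytest.raises(UnsolvableEventError):
            lv.solve_amplitude(QuadraticTerms(0.0, 0.0, 1.0))

    def test_root_policies(self):
        q = QuadraticTerms(1.0, -5.0, 6.0)  # roots 2 and 3
        assert lv.solve_amplitude(q, policy="plus")[0] == pytest.approx(3.0)
        assert lv.solve_amplitude(q, policy="minus")[0] == pytest.approx(2.0)
        assert lv.solve_amplitude(q, policy="nearest",
                                  prev_amplitude=1.9)[0] == pytest.approx(2.0)


class TestInvertSequence:
    def test_forward_inverse_round_trip(self, default_basis, mixed_plant):
        """Amplitudes of a forward-simulated RARIT are recovered identically."""
        rng = np.random.default_rng(4)
        train = lv.generate_rarit(
            lv.TrainSpec(n_trains=1, amplitude_mode="gaussian",
                         amplitude_params=(150.0, 45.0), seed=4), rng)[0]
        plant = mixed_plant.coefficients
        desired = lv.predict_output(plant, default_basis, train)
        res = lv.invert_sequence(plant, default_basis, train.times, desired)
        assert res.ok_fraction == 1.0
        np.testing.assert_allclose(res.amplitudes, train.amplitudes, rtol=1e-8)
        np.testing.assert_allclose(res.achieved_outputs, desired, rtol=1e-8)

    def test_constant_baseline_desired_gives_zero_amplitudes(
            self, default_basis, mixed_plant):
        plant = mixed_plant.coefficients
        times = np.arange(1, 20) * 0.4
        res = lv.invert_sequence(plant, default_basis, times,
                                 np.full(19, plant.c0))
        np.testing.assert_allclose(res.amplitudes, 0.0, atol=1e-10)

    def test_unreachable_target_saturates_at_vertex(
            self, default_basis, mixed_plant):
        plant = mixed_plant.coefficients
        # static maximum is at the vertex of c0 + c1p A + c2p A^2
        a_vertex = -plant.c1_present / (2 * plant.c2_present)
        y_max = (plant.c0 + plant.c1_present * a_vertex
                 + plant.c2_present * a_vertex ** 2)
        res = lv.invert_sequence(plant, default_basis, [0.0], [y_max + 0.5])
        assert res.flags == [FLAG_VERTEX]
        assert res.amplitudes[0] == pytest.approx(a_vertex)
        assert res.achieved_outputs[0] < y_max + 0.5

    def test_causality(self, default_basis, mixed_plant):
        """Amplitudes before event i ignore desired outputs at events > i."""
        plant = mixed_plant.coefficients
        rng = np.random.default_rng(6)
        times = np.cumsum(rng.uniform(0.01, 0.4, 60))
        desired = rng.uniform(0.3, 0.6, 60)
        res1 = lv.invert_sequence(plant, default_basis, times, desired)
        desired2 = desired.copy()
        desired2[30:] += 0.2
        res2 = lv.invert_sequence(plant, default_basis, times, desired2)
        np.testing.assert_array_equal(res1.amplitudes[:30],
                                      res2.amplitudes[:30])

    def test_raising_target_never_lowers_amplitude(
            self, default_basis, mixed_plant):
        plant = mixed_plant.coefficients
        times = np.cumsum(np.full(10, 0.2))
        base = np.full(10, 0.45)
        res1 = lv.invert_sequence(plant, default_basis, times, base)
        bumped = base.copy()
        bumped[4] += 0.1
        res2 = lv.invert_sequence(plant, default_basis, times, bumped)
        assert res2.amplitudes[4] >= res1.amplitudes[4]

    def test_input_validation(self, default_basis, mixed_plant):
        plant = mixed_plant.coefficients
        with pytest.raises(DataError):
            lv.invert_sequence(plant, default_basis, [0.2, 0.1], [0.4, 0.4])
        with pytest.raises(DataError):
            lv.invert_sequence(plant, default_basis, [0.1, 0.2], [0.4, np.nan])

    def test_unsolvable_event_names_index(self, default_basis):
        plant = lv.LVCoefficients(0.1, 0.0, 0.0, np.zeros(3),
                                  np.zeros((3, 3)), np.zeros(3),
                                  basis_spec=default_basis.to_spec())
        with pytest.raises(UnsolvableEventError) as exc:
            lv.invert_sequence(plant, default_basis, [0.0, 0.1], [0.1, 0.3])
        assert exc.value.index == 0

    @settings(deadline=None, max_examples=10, derandomize=True)
    @given(seed=st.integers(0, 10 ** 6))
    def test_forward_inverse_identity_property(self, seed):
        basis = lv.build_basis(0.9, 3, 300, 0.001)
        plant = lv.make_ground_truth_model("facilitating", basis).coefficients
        train = random_train(np.random.default_rng(seed), n_events=40,
                             amp_range=(60.0, 250.0))
        desired = lv.predict_output(plant, basis, train)
        res = lv.invert_sequence(plant, basis, train.times, desired)
        ok = np.array([f == FLAG_OK for f in res.flags])
        np.testing.assert_allclose(res.amplitudes[ok], train.amplitudes[ok],
                                   rtol=1e-8)


class TestControlPipeline:
    def test_noiseless_composition_matches_trajectory_predictions(
            self, default_basis):
        traj = lv.make_ground_truth_model("trajectory", default_basis, 0)
        plant = lv.make_ground_truth_model("mixed", default_basis, 0)
        rng = np.random.default_rng(5)
        stim = lv.generate_farit(lv.TrainSpec(n_trains=1, seed=5), rng)[0]
        up = lv.make_ground_truth_model("dg_upstream", default_basis, 0)
        dg = lv.EventTrain(stim.times,
                           lv.simulate_plant(up, stim).outputs,
                           amplitude_unit="mV")
        res = lv.run_control_pipeline(traj.coefficients, default_basis,
                                      plant.coefficients, default_basis, dg)
        ok = np.array([f == FLAG_OK for f in res.flags])
        assert ok.mean() > 0.99
        np.testing.assert_allclose(res.achieved_outputs[ok],
                                   res.desired_outputs[ok], rtol=1e-6)

    def test_constant_trajectory_gives_constant_inversion(self, default_basis,
                                                          mixed_plant):
        const = lv.LVCoefficients(0.5, 0.0, 0.0, np.zeros(3),
                                  np.zeros((3, 3)), np.zeros(3),
                                  basis_spec=default_basis.to_spec())
        times = np.arange(1, 11) * 1.5  # far apart: no history coupling
        dg = lv.EventTrain(times, np.linspace(0.5, 2.0, 10),
                           amplitude_unit="mV")
        res = lv.run_control_pipeline(const, default_basis,
                                      mixed_plant.coefficients,
                                      default_basis, dg)
        np.testing.assert_allclose(res.desired_outputs, 0.5)
        np.testing.assert_allclose(res.amplitudes, res.amplitudes[0],
                                   rtol=1e-6)

    def test_controlled_beats_fixed_amplitude_under_noise(self):
        wins = sum(
            (lambda r: r.controlled_nmse < r.fixed_nmse)(
                lv.run_endtoend(noise_sd=0.05, seed=seed))
            for seed in range(8))
        assert wins >= 7
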