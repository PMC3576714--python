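"""Design-matrix assembly, least-squares fitting, cross-validation."""

import numpy as np
import pytest

import lvcontrol as lv
from lvcontrol.errors import DataError, EstimationError, SingularDesignError
from lvcontrol.estimation import (design_column_names,
                                  vector_from_coefficients)

from conftest import random_coefficients, random_train


def _with_outputs(basis, coeffs, train):
    return train.with_outputs(lv.predict_output(coeffs, basis, train))


def test_design_has_15_columns_for_three_basis_functions(small_basis, rng):
    trains = [_with_outputs(small_basis, random_coefficients(rng, small_basis),
                            random_train(rng, n_events=20))]
    design = lv.build_design_matrix(small_basis, trains)
    assert design.X.shape == (20, 15)
    assert len(design.column_names) == 15
    assert design.column_names == design_column_names(3)


def test_first_event_rows_have_empty_history(small_basis, rng):
    coeffs = random_coefficients(rng, small_basis)
    trains = [_with_outputs(small_basis, coeffs, random_train(rng, train_id=t))
              for t in ("a", "b")]
    design = lv.build_design_matrix(small_basis, trains)
    for sl, train in zip(design.train_slices, trains):
        row = design.X[sl.start]
        A = train.amplitudes[0]
        np.testing.assert_allclose(row[:3], [1.0, A, A ** 2])
        np.testing.assert_array_equal(row[3:], 0.0)


def test_single_intercept_column(small_basis, rng):
    coeffs = random_coefficients(rng, small_basis)
    design = lv.build_design_matrix(
        small_basis, [_with_outputs(small_basis, coeffs, random_train(rng))])
    constant = [j for j in range(design.X.shape[1])
                if np.all(design.X[:, j] == design.X[0, j])]
    assert constant == [0]
    np.testing.assert_array_equal(design.X[:, 0], 1.0)


def test_missing_outputs_rejected(small_basis, rng):
    with pytest.raises(DataError):
        lv.build_design_matrix(small_basis, [random_train(rng)])


def test_noiseless_parameter_recovery(small_basis, rng):
    coeffs = random_coefficients(rng, small_basis)
    trains = [_with_outputs(small_basis, coeffs,
                            random_train(rng, n_events=300, train_id=f"t{k}"))
              for k in range(4)]
    report = lv.fit_trains(small_basis, trains)
    got = vector_from_coefficients(report.coefficients)
    want = vector_from_coefficients(coeffs)
    np.testing.assert_allclose(got, want, rtol=1e-6, atol=1e-12)
    assert report.n_events == 1200 and report.n_params == 15


def test_constant_outputs_give_intercept_only(small_basis, rng):
    train = random_train(rng, n_events=200).with_outputs(np.full(200, 0.37))
    report = lv.fit_trains(small_basis, [train])
    assert report.coefficients.c0 == pytest.approx(0.37, abs=1e-8)
    beta = vector_from_coefficients(report.coefficients)
    assert np.max(np.abs(beta[1:])) < 1e-8


def test_duplicate_columns_raise_singularity_error(small_basis):
    # constant amplitude makes columns const, A, A^2 collinear
    times = np.cumsum(np.full(100, 0.1))
    train = lv.EventTrain(times, np.full(100, 200.0)).with_outputs(
        np.linspace(0.3, 0.5, 100))
    design = lv.build_design_matrix(small_basis, [train])
    with pytest.raises(SingularDesignError) as exc:
        lv.fit_least_squares(design)
    assert "const" in str(exc.value) or "A" in str(exc.value)
    # with ridge the same design is solvable
    lv.fit_least_squares(design, ridge=1e-6)


def test_underdetermined_without_ridge_raises(small_basis, rng):
    coeffs = random_coefficients(rng, small_basis)
    train = _with_outputs(small_basis, coeffs, random_train(rng, n_events=10))
    with pytest.raises(EstimationError):
        lv.fit_trains(small_basis, [train])


def test_residuals_orthogonal_to_design(small_basis, rng):
    coeffs = random_coefficients(rng, small_basis)
    train = random_train(rng, n_events=400)
    noisy = lv.predict_output(coeffs, small_basis, train) \
        + rng.normal(0, 0.05, 400)
    design = lv.build_design_matrix(small_basis, [train.with_outputs(noisy)])
    report = lv.fit_least_squares(design)
    # normal equations: X^T r = 0 (checked per unit-normalized column)
    proj = (design.X.T @ report.residuals) / np.linalg.norm(design.X, axis=0)
    assert np.max(np.abs(proj)) < 1e-8


def test_recovery_unbiased_under_output_noise(small_basis):
    coeffs = random_coefficients(np.random.default_rng(0), small_basis)
    want = vector_from_coefficients(coeffs)
    estimates = []
    for rep in range(50):
        rng = np.random.default_rng(100 + rep)
        train = random_train(rng, n_events=400)
        y = lv.predict_output(coeffs, small_basis, train)
        noisy = train.with_outputs(y + rng.normal(0, 0.02, 400))
        rep_fit = lv.fit_trains(small_basis, [noisy])
        estimates.append(vector_from_coefficients(rep_fit.coefficients))
    estimates = np.asarray(estimates)
    bias = estimates.mean(axis=0) - want
    se = estimates.std(axis=0, ddof=1) / np.sqrt(50)
    assert np.all(np.abs(bias) < 4 * se + 1e-12)


class TestCrossValidation:
    def test_requires_two_trains(self, small_basis, rarit_trains):
        with pytest.raises(DataError):
            lv.cross_validate(rarit_trains[:1], [(0.8, 3, 0.12)])

    def test_fold_count_equals_train_count(self, rarit_trains):
        cv = lv.cross_validate(rarit_trains, [(0.95, 3, 1.0)])
        assert cv.best["n_folds"] == len(rarit_trains)
        assert len(cv.best["fold_vaf"]) == len(rarit_trains)

    def test_noiseless_data_with_true_basis_reaches_full_vaf(self, rarit_trains):
        cv = lv.cross_validate(rarit_trains, [(0.95, 3, 1.0)])
        assert cv.best["mean_vaf"] == pytest.approx(1.0, abs=1e-8)

    def test_true_configuration_beats_mismatched_small_model(
            self, default_basis, mixed_plant):
        rng = np.random.default_rng(9)
        spec = lv.TrainSpec(amplitude_mode="gaussian",
                            amplitude_params=(150.0, 45.0), seed=9)
        trains = []
        for t in lv.generate_rarit(spec, rng):
            clean = lv.simulate_plant(mixed_plant, t)
            trains.append(clean.with_outputs(
                clean.outputs + rng.normal(0, 0.02, t.n_events)))
        cv = lv.cross_validate(trains, [(0.95, 3, 1.0), (0.95, 1, 1.0)])
        assert cv.best["n_basis"] == 3
        held_in_l1 = lv.fit_trains(
            lv.build_basis(0.95, 1, 1000, 0.001), trains)
        # held-out VAF of the right model beats in-sample VAF of the L=1 model
        assert cv.best["mean_vaf"] > np.mean(held_in_l1.per_train_vaf)
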