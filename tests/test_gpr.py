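"""GP posterior against a dense-matrix oracle; bias correction; metrics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import neuroage as na
from neuroage.gpr import _age_stratified_folds


def dense_posterior_mean(model, X_train, y_train, X_test):
    """Independent brute-force GP posterior mean m(x*) = k*^T (K+s^2 I)^-1 y."""
    h = model.hyperparameters
    Ztr = (np.asarray(X_train, float) - model.x_mean) / model.x_scale
    Zte = (np.asarray(X_test, float) - model.x_mean) / model.x_scale

    def rbf(A, B):
        d2 = ((A[:, None, :] - B[None, :, :]) ** 2).sum(-1)
        return h["rbf_amplitude"] * np.exp(-d2 / (2 * h["rbf_length_scale"] ** 2))

    K = (
        rbf(Ztr, Ztr)
        + h["linear_variance"] * (Ztr @ Ztr.T)
        + (h["noise_variance"] + h["jitter"]) * np.eye(len(Ztr))
    )
    k_star = rbf(Zte, Ztr) + h["linear_variance"] * (Zte @ Ztr.T)
    return k_star @ np.linalg.solve(K, np.asarray(y_train, float) - model.y_mean) + model.y_mean


def test_three_point_posterior_matches_oracle():
    X = np.array([[0.0, 0.0], [1.0, 0.5], [0.2, -1.0]])
    y = np.array([40.0, 55.0, 48.0])
    cfg = na.KernelConfig(rbf_amplitude=25.0, rbf_length_scale=1.5,
                          linear_variance=2.0, noise_variance=1.0, optimize=False)
    model = na.fit_gpr(X, y, cfg)
    X_test = np.array([[0.5, 0.0], [-1.0, 1.0]])
    np.testing.assert_allclose(
        na.gpr_predict(model, X_test), dense_posterior_mean(model, X, y, X_test),
        atol=1e-10,
    )


def test_random_instances_match_oracle(rng):
    for i in range(25):
        n, d = int(rng.integers(3, 51)), int(rng.integers(1, 9))
        X = rng.normal(size=(n, d))
        y = rng.normal(50, 10, n)
        cfg = na.KernelConfig(
            rbf_amplitude=float(rng.uniform(1, 100)),
            rbf_length_scale=float(rng.uniform(0.5, 5)),
            linear_variance=float(rng.uniform(0.1, 5)),
            noise_variance=float(rng.uniform(0.1, 5)),
            optimize=False,
        )
        model = na.fit_gpr(X, y, cfg)
        X_test = rng.normal(size=(6, d))
        np.testing.assert_allclose(
            na.gpr_predict(model, X_test), dense_posterior_mean(model, X, y, X_test),
            atol=1e-8,
        )


def test_vanishing_noise_interpolates_targets(rng):
    X = rng.normal(size=(8, 3))
    y = rng.normal(50, 10, 8)
    model = na.fit_gpr(X, y, na.KernelConfig(noise_variance=1e-10, optimize=False))
    np.testing.assert_allclose(na.gpr_predict(model, X), y, atol=1e-6)


def test_constant_targets_predict_constant(rng):
    X = rng.normal(size=(30, 4))
    y = np.full(30, 62.0)
    model = na.fit_gpr(X, y, na.KernelConfig(n_restarts=1, seed=0))
    np.testing.assert_allclose(na.gpr_predict(model, rng.normal(size=(5, 4))), 62.0,
                               atol=1e-6)


def test_predict_is_row_equivariant(small_gpr, clinical_table):
    table, _ = clinical_table
    X = table[list(na.FEATURE_COLUMNS)].to_numpy()[:10]
    pred = na.gpr_predict(small_gpr, X)
    perm = np.array([3, 1, 4, 0, 2, 9, 8, 7, 6, 5])
    np.testing.assert_allclose(na.gpr_predict(small_gpr, X[perm]), pred[perm],
                               rtol=0, atol=1e-10)
    dup = np.vstack([X[0], X[0]])
    out = na.gpr_predict(small_gpr, dup)
    assert out[0] == pytest.approx(out[1], abs=1e-12)


def test_schema_mismatch_raises(small_gpr, clinical_table):
    table, _ = clinical_table
    with pytest.raises(KeyError):
        na.gpr_predict(small_gpr, table.drop(columns=["thickness__VIS"]))
    with pytest.raises(ValueError):
        na.gpr_predict(small_gpr, np.zeros((3, 5)))


def test_cross_validation_partitions_and_is_deterministic(training_table):
    table, _ = training_table
    sub = table.iloc[:10]
    cfg = na.KernelConfig(optimize=False)
    loo = na.cross_validate(sub, folds=10, seed=0, config=cfg)
    counts = np.bincount(loo.fold_assignment, minlength=10)
    assert (counts == 1).all()
    assert np.isfinite(loo.oof["predicted_age"]).all()
    again = na.cross_validate(sub, folds=10, seed=0, config=cfg)
    np.testing.assert_array_equal(loo.fold_assignment, again.fold_assignment)
    other = na.cross_validate(sub, folds=5, seed=1, config=cfg)
    assert np.bincount(other.fold_assignment, minlength=5).sum() == 10
    with pytest.raises(ValueError):
        na.cross_validate(sub, folds=1)
    with pytest.raises(ValueError):
        na.cross_validate(sub.iloc[:3], folds=5)


def test_fold_assignment_stratifies_age(training_table):
    table, _ = training_table
    ages = table["age"].to_numpy()
    folds = _age_stratified_folds(ages, 5, seed=0)
    fold_means = [ages[folds == f].mean() for f in range(5)]
    assert max(fold_means) - min(fold_means) < 5.0


def test_perfect_mapping_recovers_age():
    rng = np.random.default_rng(0)
    age = rng.uniform(40, 90, 80)
    table = pd.DataFrame({"participant_id": range(80), "age": age})
    # age is an exact, invertible smooth function of one feature; the rest
    # carry nothing
    for j, key in enumerate(na.FEATURE_COLUMNS):
        table[key] = np.sqrt(age) if j == 0 else 0.0
    cv = na.cross_validate(table, folds=5, seed=0,
                           config=na.KernelConfig(n_restarts=1, seed=0))
    assert cv.metrics_raw.mae < 0.5


def test_bias_correction_closed_form():
    age = np.linspace(30, 80, 40)
    predicted = 0.5 * age + 30.0
    corr = na.fit_bias_correction(age, predicted)
    assert corr.slope == pytest.approx(-0.5, abs=1e-10)
    assert corr.intercept == pytest.approx(30.0, abs=1e-9)
    bag = corr.apply(age, predicted) - age
    slope_after = np.polyfit(age, bag, 1)[0]
    assert abs(slope_after) < 1e-10

    ident = na.fit_bias_correction(age, age)
    assert ident.slope == pytest.approx(0.0, abs=1e-12)
    assert ident.intercept == pytest.approx(0.0, abs=1e-10)


@given(shift=st.floats(-30, 30))
@settings(deadline=None, max_examples=25)
def test_bias_correction_translation_equivariance(shift):
    age = np.linspace(30, 80, 20)
    predicted = 0.8 * age + 5.0
    base = na.fit_bias_correction(age, predicted)
    moved = na.fit_bias_correction(age, predicted + shift)
    assert moved.slope == pytest.approx(base.slope, abs=1e-9)
    assert moved.intercept == pytest.approx(base.intercept + shift, abs=1e-8)


def test_bias_correction_degenerate_inputs():
    with pytest.raises(ValueError):
        na.fit_bias_correction(np.arange(5), np.arange(5))
    with pytest.raises(ValueError):
        na.fit_bias_correction(np.full(20, 50.0), np.arange(20.0))


def test_compute_bag_identity_and_errors():
    ages = np.array([40.0, 50.0, 60.0])
    records = na.compute_bag(["a", "b", "c"], ages, ages + 5.0)
    np.testing.assert_allclose(records["bag"], 5.0)
    np.testing.assert_allclose(
        records["corrected_predicted_age"] - records["age"], records["bag"]
    )
    empty = na.compute_bag([], [], [])
    assert len(empty) == 0
    with pytest.raises(ValueError):
        na.compute_bag(["a"], [40.0, 50.0], [41.0, 51.0])


def test_prediction_metrics_arithmetic():
    m = na.prediction_metrics([30, 40, 50], [32, 38, 53])
    assert m.mae == pytest.approx(7.0 / 3.0)
    perfect = na.prediction_metrics([30, 40, 50], [30, 40, 50])
    assert perfect.mae == 0.0 and perfect.r_squared == pytest.approx(1.0)
    # squared correlation is blind to sign: documented behavior
    anti = na.prediction_metrics([30, 40, 50], [50, 40, 30])
    assert anti.r_squared == pytest.approx(1.0)
    grouped = na.prediction_metrics(
        [30, 40, 50, 60], [31, 41, 55, 65], group_labels=[0, 0, 1, 1]
    )
    assert grouped.group_mae[0] == pytest.approx(1.0)
    assert grouped.group_mae[1] == pytest.approx(5.0)
    with pytest.raises(ValueError):
        na.prediction_metrics([30], [31])
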