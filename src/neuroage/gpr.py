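"""Gaussian-process normative age model, bias correction, and brain-age gap.

The normative model is a Gaussian-process regression from the 28
harmonized morphometric features to chronological age, with an
RBF + linear + white-noise covariance on standardized features (the RBF
term captures smooth nonlinear aging, the linear term the global trend).
Hyperparameters are set by maximizing the log marginal likelihood with
seeded multi-start optimization.

The brain-age gap (BAG) is corrected predicted age minus chronological
age. Because regression to the mean makes raw predicted age too young in
old participants and too old in young ones, the gap is bias-corrected by
regressing out-of-fold (predicted - chronological) on chronological age in
the training cohort and subtracting the fitted line; the corrected
training BAG is then exactly age-orthogonal, and the same training-derived
coefficients are applied to any test cohort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, DotProduct, WhiteKernel

from .features import FEATURE_COLUMNS

__all__ = [
    "KernelConfig",
    "GprModel",
    "BiasCorrection",
    "CvMetrics",
    "fit_gpr",
    "gpr_predict",
    "cross_validate",
    "fit_bias_correction",
    "compute_bag",
    "prediction_metrics",
]


@dataclass
class KernelConfig:
    """Covariance hyperparameters (initial values when optimizing).

    Amplitudes and variances are in squared target units (years^2) on
    standardized features; the length-scale is in standardized feature
    units. With ``optimize=False`` the values are used as-is, which makes
    the posterior mean directly comparable to a dense linear-algebra
    oracle.
    """

    rbf_amplitude: float = 100.0
    rbf_length_scale: float = 10.0
    linear_variance: float = 1.0
    noise_variance: float = 10.0
    optimize: bool = True
    n_restarts: int = 5
    seed: int = 0


@dataclass
class GprModel:
    """Fitted GP state: sklearn regressor plus standardization parameters."""

    gp: GaussianProcessRegressor
    feature_names: list
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    hyperparameters: dict = field(default_factory=dict)


def _feature_array(X, feature_names=None):
    if isinstance(X, pd.DataFrame):
        cols = feature_names if feature_names is not None else [
            c for c in FEATURE_COLUMNS if c in X.columns
        ]
        missing = [c for c in cols if c not in X.columns]
        if missing:
            raise KeyError(f"feature column(s) missing: {missing}")
        return X[cols].to_numpy(float), list(cols)
    arr = np.asarray(X, float)
    if feature_names is not None and arr.shape[1] != len(feature_names):
        raise ValueError(
            f"expected {len(feature_names)} features, got {arr.shape[1]}"
        )
    names = feature_names if feature_names is not None else [f"x{j}" for j in range(arr.shape[1])]
    return arr, list(names)


def fit_gpr(X, y, config: KernelConfig | None = None) -> GprModel:
    """Fit the GP age model (RBF + linear + white noise).

    Features are standardized with training statistics and the target is
    centered, so the prior mean is the training mean age. A small jitter
    is added to the kernel diagonal before factorization, escalating
    tenfold (up to 1e-2) if the Cholesky decomposition fails.
    """
    config = config or KernelConfig()
    y = np.asarray(y, float)
    Xa, names = _feature_array(X)
    if config.optimize and len(y) < 20:
        raise ValueError("need at least 20 rows to optimize hyperparameters")
    x_mean = Xa.mean(axis=0)
    x_scale = Xa.std(axis=0)
    x_scale[x_scale == 0] = 1.0
    Z = (Xa - x_mean) / x_scale
    y_mean = float(y.mean())
    kernel = (
        ConstantKernel(config.rbf_amplitude, (1e-3, 1e6))
        * RBF(config.rbf_length_scale, (1e-2, 1e4))
        + ConstantKernel(config.linear_variance, (1e-6, 1e4))
        * DotProduct(sigma_0=0.0, sigma_0_bounds="fixed")
        + WhiteKernel(config.noise_variance, (1e-8, 1e4))
    )
    jitter = 1e-10
    last_err = None
    while jitter <= 1e-2:
        gp = GaussianProcessRegressor(
            kernel=kernel,
            alpha=jitter,
            optimizer="fmin_l_bfgs_b" if config.optimize else None,
            n_restarts_optimizer=config.n_restarts if config.optimize else 0,
            normalize_y=False,
            random_state=config.seed,
        )
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                gp.fit(Z, y - y_mean)
            break
        except np.linalg.LinAlgError as err:  # pragma: no cover - conditioning fallback
            last_err = err
            jitter *= 10.0
    else:  # pragma: no cover
        raise np.linalg.LinAlgError(f"kernel matrix not factorizable: {last_err}")
    k = gp.kernel_
    hyper = {
        "rbf_amplitude": float(k.k1.k1.k1.constant_value),
        "rbf_length_scale": float(k.k1.k1.k2.length_scale),
        "linear_variance": float(k.k1.k2.k1.constant_value),
        "noise_variance": float(k.k2.noise_level),
        "log_marginal_likelihood": float(gp.log_marginal_likelihood_value_),
        "jitter": jitter,
    }
    return GprModel(gp=gp, feature_names=names, x_mean=x_mean, x_scale=x_scale,
                    y_mean=y_mean, hyperparameters=hyper)


def gpr_predict(model: GprModel, X) -> np.ndarray:
    """Posterior-mean predicted ages for new rows (deterministic)."""
    Xa, _ = _feature_array(X, model.feature_names)
    if Xa.shape[0] == 0:
        return np.zeros(0)
    Z = (Xa - model.x_mean) / model.x_scale
    return model.gp.predict(Z) + model.y_mean


@dataclass
class BiasCorrection:
    """OLS fit of (predicted - chronological) on chronological age."""

    intercept: float
    slope: float

    def apply(self, chronological: np.ndarray, predicted: np.ndarray) -> np.ndarray:
        chronological = np.asarray(chronological, float)
        return np.asarray(predicted, float) - (self.intercept + self.slope * chronological)


def fit_bias_correction(chronological, predicted) -> BiasCorrection:
    """Estimate the age-bias line from out-of-fold training predictions."""
    chronological = np.asarray(chronological, float)
    predicted = np.asarray(predicted, float)
    if len(chronological) < 10:
        raise ValueError("bias correction needs at least 10 points")
    if np.ptp(chronological) == 0:
        raise ValueError("chronological age has zero variance")
    gap = predicted - chronological
    slope, intercept = np.polyfit(chronological, gap, 1)
    return BiasCorrection(intercept=float(intercept), slope=float(slope))


def compute_bag(
    participant_ids,
    ages,
    predicted,
    correction: BiasCorrection | None = None,
) -> pd.DataFrame:
    """Per-participant BAG records (corrected predicted minus chronological).

    ``correction`` must carry training-derived coefficients; ``None``
    applies the identity correction.
    """
    ages = np.asarray(ages, float)
    predicted = np.asarray(predicted, float)
    ids = list(participant_ids)
    if not len(ids) == len(ages) == len(predicted):
        raise ValueError("participant_ids, ages, and predicted must align")
    correction = correction or BiasCorrection(0.0, 0.0)
    corrected = correction.apply(ages, predicted)
    return pd.DataFrame(
        {
            "participant_id": ids,
            "age": ages,
            "predicted_age": predicted,
            "corrected_predicted_age": corrected,
            "bag": corrected - ages,
        }
    )


@dataclass
class CvMetrics:
    """Accuracy summary: pooled and per-fold MAE, squared Pearson r."""

    mae: float
    r_squared: float
    fold_mae: list = field(default_factory=list)
    fold_r_squared: list = field(default_factory=list)
    group_mae: dict = field(default_factory=dict)
    group_r_squared: dict = field(default_factory=dict)


def prediction_metrics(ages, predicted, group_labels=None) -> CvMetrics:
    """MAE and squared Pearson correlation, optionally per group."""
    ages = np.asarray(ages, float)
    predicted = np.asarray(predicted, float)
    if len(ages) < 2:
        raise ValueError("metrics need at least two observations")
    mae = float(np.mean(np.abs(predicted - ages)))
    r2 = float(stats.pearsonr(ages, predicted)[0] ** 2)
    metrics = CvMetrics(mae=mae, r_squared=r2)
    if group_labels is not None:
        groups = np.asarray(group_labels)
        for g in np.unique(groups):
            mask = groups == g
            metrics.group_mae[g] = float(np.mean(np.abs(predicted[mask] - ages[mask])))
            if mask.sum() >= 2:
                metrics.group_r_squared[g] = float(
                    stats.pearsonr(ages[mask], predicted[mask])[0] ** 2
                )
    return metrics


def _age_stratified_folds(ages: np.ndarray, folds: int, seed: int) -> np.ndarray:
    """Fold labels balanced across age quantile strata (deterministic)."""
    rng = np.random.default_rng(seed)
    order = np.argsort(ages, kind="stable")
    assignment = np.empty(len(ages), dtype=int)
    for start in range(0, len(ages), folds):
        stratum = order[start : start + folds]
        labels = rng.permutation(folds)[: len(stratum)]
        assignment[stratum] = labels
    return assignment


@dataclass
class CvResult:
    """Cross-validation output: metrics, out-of-fold predictions, correction."""

    metrics_raw: CvMetrics
    metrics_corrected: CvMetrics
    oof: pd.DataFrame
    bias_correction: BiasCorrection
    fold_assignment: np.ndarray


def cross_validate(
    table: pd.DataFrame,
    folds: int = 5,
    seed: int = 0,
    config: KernelConfig | None = None,
    age_col: str = "age",
    feature_cols=FEATURE_COLUMNS,
) -> CvResult:
    """Age-stratified k-fold cross-validation of the GP age model.

    Fold assignment stratifies on age quantiles so each fold spans the
    age range. Every row is predicted exactly once out-of-fold; the bias
    correction is fitted on the pooled out-of-fold predictions, and
    metrics are reported before and after correction.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if len(table) < folds:
        raise ValueError("need at least as many rows as folds")
    ages = table[age_col].to_numpy(float)
    assignment = _age_stratified_folds(ages, folds, seed)
    predicted = np.full(len(table), np.nan)
    fold_mae, fold_r2 = [], []
    feature_cols = [c for c in feature_cols if c in table.columns]
    for f in range(folds):
        test = assignment == f
        model = fit_gpr(table.loc[~test, feature_cols], ages[~test], config)
        predicted[test] = gpr_predict(model, table.loc[test, feature_cols])
        if test.sum() >= 2:
            m = prediction_metrics(ages[test], predicted[test])
            fold_mae.append(m.mae)
            fold_r2.append(m.r_squared)
    correction = fit_bias_correction(ages, predicted)
    corrected = correction.apply(ages, predicted)
    groups = table["group"].to_numpy() if "group" in table.columns else None
    metrics_raw = prediction_metrics(ages, predicted, groups)
    metrics_raw.fold_mae = fold_mae
    metrics_raw.fold_r_squared = fold_r2
    metrics_corr = prediction_metrics(ages, corrected, groups)
    oof = pd.DataFrame(
        {
            "participant_id": table.get("participant_id", pd.RangeIndex(len(table))),
            "age": ages,
            "predicted_age": predicted,
            "corrected_predicted_age": corrected,
            "bag": corrected - ages,
            "fold": assignment,
        }
    )
    return CvResult(
        metrics_raw=metrics_raw,
        metrics_corrected=metrics_corr,
        oof=oof,
        bias_correction=correction,
        fold_assignment=assignment,
    )
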