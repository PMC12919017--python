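"""Shapley attribution of predicted brain age with age-matched baselines.

Each participant's predicted age is decomposed into signed per-feature
contributions (in years) relative to a reference baseline built from the
k = 10 training participants closest in age to that participant. The
coalition value function is interventional: v(S) is the model prediction
averaged over the k reference rows with the participant's own values
substituted on the coalition S. Shapley values are estimated by antithetic
permutation sampling of marginal contributions, which enforces the
efficiency axiom (contributions along one permutation telescope to
f(x) - baseline) by construction; an exact enumeration oracle over all
2^d coalitions is provided for small d.

Positive values indicate features pushing the prediction toward older age,
negative values toward younger age. Global importance is the mean absolute
value across participants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import FEATURE_COLUMNS, parse_feature_key
from .gpr import GprModel, gpr_predict

__all__ = [
    "ReferenceSet",
    "ShapMatrix",
    "ImportanceSummary",
    "select_reference_set",
    "shapley_attribution",
    "exact_shapley_oracle",
    "attribute_cohort",
    "global_importance",
    "aggregate_signed_shap",
]


@dataclass
class ReferenceSet:
    """The k training rows nearest in age to a target participant."""

    target_id: str
    k: int
    indices: np.ndarray
    features: np.ndarray  # (k, d)
    ages: np.ndarray
    baseline: float | None = None  # mean model prediction over the k rows


def select_reference_set(
    target_age: float,
    training_table: pd.DataFrame,
    k: int = 10,
    target_id: str = "",
    feature_cols=None,
    model: GprModel | None = None,
) -> ReferenceSet:
    """Pick the k training participants closest in age to ``target_age``.

    Ties in age distance are broken by ascending participant id (then row
    order), so selection is deterministic. If ``model`` is given, the
    baseline (mean prediction over the k rows) is filled in.
    """
    if k > len(training_table):
        raise ValueError(f"k={k} exceeds training size {len(training_table)}")
    cols = list(feature_cols) if feature_cols is not None else [
        c for c in FEATURE_COLUMNS if c in training_table.columns
    ]
    ages = training_table["age"].to_numpy(float)
    dist = np.abs(ages - target_age)
    ids = (
        training_table["participant_id"].astype(str).to_numpy()
        if "participant_id" in training_table.columns
        else np.arange(len(training_table)).astype(str)
    )
    order = np.lexsort((np.arange(len(ages)), ids, dist))
    chosen = order[:k]
    features = training_table.iloc[chosen][cols].to_numpy(float)
    ref = ReferenceSet(
        target_id=target_id,
        k=k,
        indices=chosen,
        features=features,
        ages=ages[chosen],
    )
    if model is not None:
        ref.baseline = float(np.mean(gpr_predict(model, features)))
    return ref


def _as_predict_fn(model):
    if callable(model) and not isinstance(model, GprModel):
        return lambda X: np.asarray(model(np.asarray(X, float)), float)
    return lambda X: gpr_predict(model, X)


def shapley_attribution(
    model,
    x,
    ref: ReferenceSet,
    n_permutations: int = 512,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Sampled Shapley values and their Monte-Carlo standard errors.

    Permutations are drawn in antithetic pairs (a permutation and its
    reverse); the estimate averages marginal contributions over pairs and
    the standard error treats each pair as one independent draw. ``model``
    may be a fitted :class:`~neuroage.gpr.GprModel` or any callable on
    2-D arrays.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    predict = _as_predict_fn(model)
    x = np.asarray(x, float).ravel()
    d = x.size
    if ref.features.shape[1] != d:
        raise ValueError("reference set and target row have different widths")
    rng = np.random.default_rng(seed)
    n_pairs = max(1, (n_permutations + 1) // 2)
    pair_contrib = np.empty((n_pairs, d))
    k = ref.features.shape[0]
    for i in range(n_pairs):
        perm = rng.permutation(d)
        contribs = np.empty((2, d))
        for j, order in enumerate((perm, perm[::-1])):
            # chain of hybrid rows: start at the references, reveal x's
            # features one at a time in permutation order
            chain = np.repeat(ref.features[None, :, :], d + 1, axis=0).copy()
            for step, feat in enumerate(order):
                chain[step + 1 :, :, feat] = x[feat]
            values = predict(chain.reshape(-1, d)).reshape(d + 1, k).mean(axis=1)
            contribs[j, order] = np.diff(values)
        pair_contrib[i] = contribs.mean(axis=0)
    phi = pair_contrib.mean(axis=0)
    if n_pairs > 1:
        se = pair_contrib.std(axis=0, ddof=1) / np.sqrt(n_pairs)
    else:
        se = np.zeros(d)
    return phi, se


def exact_shapley_oracle(model, x, ref: ReferenceSet) -> np.ndarray:
    """Exact Shapley values by enumeration over all 2^d coalitions (d <= 15)."""
    predict = _as_predict_fn(model)
    x = np.asarray(x, float).ravel()
    d = x.size
    if d > 15:
        raise ValueError("exact enumeration limited to d <= 15 features")
    k = ref.features.shape[0]
    n_sets = 1 << d
    hybrids = np.repeat(ref.features[None, :, :], n_sets, axis=0)
    masks = (np.arange(n_sets)[:, None] >> np.arange(d)) & 1
    for feat in range(d):
        hybrids[masks[:, feat] == 1, :, feat] = x[feat]
    values = predict(hybrids.reshape(-1, d)).reshape(n_sets, k).mean(axis=1)
    sizes = masks.sum(axis=1)
    from math import factorial

    weight_by_size = np.array(
        [factorial(s) * factorial(d - s - 1) / factorial(d) for s in range(d)]
    )
    phi = np.zeros(d)
    for feat in range(d):
        without = masks[:, feat] == 0
        s_masks = np.flatnonzero(without)
        phi[feat] = np.sum(
            weight_by_size[sizes[s_masks]]
            * (values[s_masks | (1 << feat)] - values[s_masks])
        )
    return phi


@dataclass
class ShapMatrix:
    """Participants x features signed Shapley values plus metadata."""

    values: pd.DataFrame  # index participant_id, columns features
    mc_se: pd.DataFrame
    baseline: pd.Series
    prediction: pd.Series
    k: int
    n_permutations: int
    seed: int


def attribute_cohort(
    model: GprModel,
    table: pd.DataFrame,
    training_table: pd.DataFrame,
    k: int = 10,
    n_permutations: int = 512,
    seed: int = 0,
) -> ShapMatrix:
    """Signed Shapley values for every participant in ``table``.

    Each participant gets their own age-matched reference set; the
    per-participant sampling seed is derived from ``seed`` so the result
    is reproducible and independent of row order.
    """
    cols = model.feature_names
    values, ses, baselines, preds = [], [], [], []
    ids = table["participant_id"].astype(str).tolist()
    predictions = gpr_predict(model, table[cols])
    for i, (_, row) in enumerate(table.iterrows()):
        ref = select_reference_set(
            float(row["age"]), training_table, k=k, target_id=ids[i],
            feature_cols=cols, model=model,
        )
        phi, se = shapley_attribution(
            model, row[cols].to_numpy(float), ref,
            n_permutations=n_permutations, seed=seed + 7919 * i,
        )
        values.append(phi)
        ses.append(se)
        baselines.append(ref.baseline)
        preds.append(predictions[i])
    return ShapMatrix(
        values=pd.DataFrame(values, index=ids, columns=cols),
        mc_se=pd.DataFrame(ses, index=ids, columns=cols),
        baseline=pd.Series(baselines, index=ids, name="baseline"),
        prediction=pd.Series(preds, index=ids, name="prediction"),
        k=k,
        n_permutations=n_permutations,
        seed=seed,
    )


@dataclass
class ImportanceSummary:
    """Global importance: mean |phi| per feature and per network x measure."""

    per_feature: pd.Series
    per_cell: pd.DataFrame  # measure, network, importance, rank within measure


def global_importance(shap: ShapMatrix) -> ImportanceSummary:
    if len(shap.values) < 1:
        raise ValueError("need at least one participant")
    per_feature = shap.values.abs().mean(axis=0)
    rows = []
    for key, imp in per_feature.items():
        measure, network = parse_feature_key(key)
        rows.append({"measure": measure, "network": network, "importance": float(imp)})
    cells = pd.DataFrame(rows)
    cells["rank_within_measure"] = (
        cells.groupby("measure")["importance"].rank(ascending=False, method="min").astype(int)
    )
    return ImportanceSummary(per_feature=per_feature, per_cell=cells)


def aggregate_signed_shap(shap: ShapMatrix, table: pd.DataFrame) -> pd.DataFrame:
    """Long table (participant x network x measure) for mixed-effects tests.

    Each network x measure cell holds the signed Shapley value of its
    single feature; group labels and covariates are carried along so the
    result feeds directly into :func:`neuroage.inference.signed_shap_lme`.
    """
    ids = set(shap.values.index)
    tids = set(table["participant_id"].astype(str))
    if ids != tids:
        raise ValueError("participant ids of the Shapley matrix and table differ")
    long = shap.values.reset_index(names="participant_id").melt(
        id_vars="participant_id", var_name="feature", value_name="shap"
    )
    parsed = long["feature"].map(parse_feature_key)
    long["measure"] = parsed.str[0]
    long["network"] = parsed.str[1]
    carry = [
        c for c in ("group", "hiv", "cu", "nci", "age", "sex", "education",
                    "zung", "euler", "motion")
        if c in table.columns
    ]
    meta = table[["participant_id"] + carry].copy()
    meta["participant_id"] = meta["participant_id"].astype(str)
    return long.merge(meta, on="participant_id", how="left").drop(columns=["feature"])
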