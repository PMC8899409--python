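"""Predicting per-OR responses from molecular descriptors.

The QSAR-style question: given a large panel of numeric molecular
descriptors for each odorant, how well can a regressor predict the
response of each OR to held-out odorants?  The pipeline is

1. a descriptor filtering cascade (drop descriptors with missing
   values, near-zero variance, or high mutual correlation),
2. a random 70/15/15 odorant split into train / validation / test,
3. one small feedforward network per OR (three hidden layers of 50
   units), trained on the training odorants with the validation
   odorants driving early stopping,
4. a shuffled-response control: the OR x odorant response matrix is
   globally permuted and read back as "predictions", giving the
   no-structure baseline, and
5. per-OR evaluation (Pearson R and mean absolute error on the test
   odorants) with a paired sign-rank comparison of model vs control
   across ORs.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field as dataclass_field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPRegressor

from .errors import ConfigError, EmptySelectionError

#: Hidden-layer architecture of the per-OR network.
DEFAULT_ARCH = (50, 50, 50)

#: Training-schedule defaults (the architecture is fixed by design; these
#: knobs are ordinary fitting hyperparameters, all seedable).  Training
#: runs in stages of L-BFGS iterations; the validation loss is measured
#: after each stage and the best-validation weights are kept.
TRAIN_DEFAULTS = {
    "stage_iters": 300,    # optimizer iterations per validation check
    "max_stages": 6,
    "patience": 2,         # stop after this many stages without improvement
    "alpha": 1.0,          # L2 penalty; odorant panels are small, so strong
    "activation": "tanh",  # smooth tuning surfaces suit saturating units
}


def filter_descriptors(
    matrix: pd.DataFrame, var_min: float = 0.005, corr_max: float = 0.95
) -> pd.DataFrame:
    """Descriptor filtering cascade.

    Stages, in order: (1) drop any descriptor with a missing value;
    (2) drop descriptors with variance < ``var_min`` (computed on the
    raw, unstandardized values — the threshold is scale-dependent by
    construction); (3) greedily scan the survivors in input order,
    dropping any descriptor whose absolute Pearson correlation with an
    already-retained descriptor exceeds ``corr_max`` (keep-first
    tie-break, so the result is reproducible from the input file).
    Column order is preserved; the cascade never adds columns, so it is
    idempotent.
    """
    m = matrix.loc[:, ~matrix.isna().any(axis=0)]
    variances = m.var(axis=0, ddof=1)
    m = m.loc[:, variances >= var_min]
    if m.shape[1] == 0:
        raise EmptySelectionError("no descriptors survive the missing/variance stages")
    values = m.to_numpy(float)
    corr = np.corrcoef(values, rowvar=False)
    if corr.ndim == 0:
        corr = np.array([[1.0]])
    kept: list[int] = []
    for j in range(values.shape[1]):
        if all(abs(corr[j, k]) <= corr_max for k in kept):
            kept.append(j)
    if not kept:
        raise EmptySelectionError("no descriptors survive the correlation stage")
    return m.iloc[:, kept]


def split_odorants(
    odorants: list[str],
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int = 0,
) -> tuple[list[str], list[str], list[str]]:
    """Random train / validation / test partition of the odorant panel.

    Sizes: validation and test are rounded to the nearest integer, the
    remainder goes to train, so the parts are disjoint and exhaustive
    (112 odorants at 70/15/15 gives 78/17/17).
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ConfigError(f"split fractions must sum to 1, got {fractions}")
    if any(f < 0 for f in fractions):
        raise ConfigError("split fractions must be non-negative")
    n = len(odorants)
    if n < 10:
        raise ConfigError(f"need at least 10 odorants to split, got {n}")
    n_val = round(n * fractions[1])
    n_test = round(n * fractions[2])
    if n_val + n_test >= n:
        raise ConfigError("validation+test would leave no training odorants")
    order = np.random.default_rng(seed).permutation(n)
    odorants = list(odorants)
    val = [odorants[i] for i in order[:n_val]]
    test = [odorants[i] for i in order[n_val:n_val + n_test]]
    train = [odorants[i] for i in order[n_val + n_test:]]
    return train, val, test


@dataclass
class ORModel:
    """A trained per-OR regressor with its input/output standardization."""

    net: MLPRegressor
    mean: np.ndarray
    scale: np.ndarray
    y_mean: float
    y_scale: float
    n_stages: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        Xs = (np.asarray(X, float) - self.mean) / self.scale
        return self.net.predict(Xs) * self.y_scale + self.y_mean


def train_or_model(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    arch: tuple[int, ...] = DEFAULT_ARCH,
    seed: int = 0,
    **train_kwargs,
) -> ORModel:
    """Train one OR's feedforward network with validation early stopping.

    Inputs and the response are standardized on the training set (the
    filter's variance threshold has already been applied on the raw
    scale).  The L-BFGS optimizer runs in stages of ``stage_iters``
    iterations; after each stage the validation MSE is measured and the
    best-validation weights are kept; training stops after ``patience``
    stages without improvement or at the stage cap.  Deterministic given
    ``seed``.
    """
    params = {**TRAIN_DEFAULTS, **train_kwargs}
    X_train = np.asarray(X_train, float)
    X_val = np.asarray(X_val, float)
    y_train = np.asarray(y_train, float)
    y_val = np.asarray(y_val, float)
    if not (
        np.isfinite(X_train).all() and np.isfinite(y_train).all()
        and np.isfinite(X_val).all() and np.isfinite(y_val).all()
    ):
        raise ValueError("non-finite descriptor or response values")
    mean = X_train.mean(axis=0)
    scale = X_train.std(axis=0)
    scale[scale == 0] = 1.0
    Xt = (X_train - mean) / scale
    Xv = (X_val - mean) / scale
    y_mean = float(y_train.mean())
    y_scale = float(y_train.std()) or 1.0
    yt = (y_train - y_mean) / y_scale

    net = MLPRegressor(
        hidden_layer_sizes=tuple(arch),
        random_state=seed,
        solver="lbfgs",
        activation=params["activation"],
        alpha=params["alpha"],
        max_iter=params["stage_iters"],
        warm_start=True,
    )
    best_loss = np.inf
    best_state = None
    best_stage = 0
    since_best = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for stage in range(1, params["max_stages"] + 1):
            net.fit(Xt, yt)
            val_pred = net.predict(Xv) * y_scale + y_mean
            val_loss = float(np.mean((val_pred - y_val) ** 2))
            if val_loss < best_loss:
                best_loss = val_loss
                best_state = (
                    copy.deepcopy(net.coefs_), copy.deepcopy(net.intercepts_)
                )
                best_stage = stage
                since_best = 0
            else:
                since_best += 1
                if since_best >= params["patience"]:
                    break
    net.coefs_, net.intercepts_ = best_state
    return ORModel(
        net=net, mean=mean, scale=scale, y_mean=y_mean, y_scale=y_scale,
        n_stages=best_stage,
    )


def control_predictions(
    response_matrix: pd.DataFrame, seed: int = 0, per_row: bool = False
) -> pd.DataFrame:
    """Shuffled-response control matrix.

    Globally permutes the entries of the OR x odorant response matrix
    (or each row independently with ``per_row=True``); reading an OR's
    row at the test odorants then yields structure-free "predictions"
    that conserve the overall multiset of response values.
    """
    rng = np.random.default_rng(seed)
    values = response_matrix.to_numpy(float).copy()
    if per_row:
        for i in range(values.shape[0]):
            values[i] = values[i, rng.permutation(values.shape[1])]
    else:
        flat = values.ravel()
        values = flat[rng.permutation(flat.size)].reshape(values.shape)
    return pd.DataFrame(
        values, index=response_matrix.index, columns=response_matrix.columns
    )


@dataclass
class PredictionResult:
    """Per-OR test metrics for model and control, plus their comparison."""

    per_or: dict[str, dict] = dataclass_field(default_factory=dict)
    control_per_or: dict[str, dict] = dataclass_field(default_factory=dict)
    comparison_p: float | None = None
    comparison_p_error: float | None = None
    split_seed: int | None = None

    def median_r(self, control: bool = False) -> float:
        src = self.control_per_or if control else self.per_or
        rs = [v["pearson_r"] for v in src.values() if v["pearson_r"] is not None]
        return float(np.median(rs))

    def to_dict(self) -> dict:
        return {
            "per_or": self.per_or,
            "control_per_or": self.control_per_or,
            "comparison_p": self.comparison_p,
            "comparison_p_error": self.comparison_p_error,
            "split_seed": self.split_seed,
        }


def evaluate_predictions(
    predicted: pd.DataFrame,
    control_predicted: pd.DataFrame,
    actual: pd.DataFrame,
    split_seed: int | None = None,
) -> PredictionResult:
    """Per-OR Pearson R and mean absolute error, model vs control.

    All three frames are OR x test-odorant.  An OR whose actual test
    responses have zero variance gets ``pearson_r = None`` (flagged, not
    silently dropped); MAE is always defined.  The across-OR comparison
    is a two-sided paired sign-rank test on the per-OR R values (and,
    separately, on the per-OR errors).
    """
    from .stats import sign_rank_test

    if predicted.shape[1] < 3:
        raise EmptySelectionError("need >= 3 test odorants per OR for a correlation")
    result = PredictionResult(split_seed=split_seed)
    for frame, target in (
        (predicted, result.per_or), (control_predicted, result.control_per_or)
    ):
        for or_name in actual.index:
            y = actual.loc[or_name].to_numpy(float)
            yhat = frame.loc[or_name].to_numpy(float)
            if np.std(y) == 0 or np.std(yhat) == 0:
                r = None
            else:
                r = float(stats.pearsonr(yhat, y).statistic)
            target[or_name] = {
                "pearson_r": r,
                "mean_abs_error": float(np.mean(np.abs(yhat - y))),
            }
    rs = [
        (result.per_or[o]["pearson_r"], result.control_per_or[o]["pearson_r"])
        for o in actual.index
        if result.per_or[o]["pearson_r"] is not None
        and result.control_per_or[o]["pearson_r"] is not None
    ]
    if len(rs) >= 2:
        model_r, control_r = map(np.array, zip(*rs))
        result.comparison_p = sign_rank_test(model_r - control_r).p_value
        errs = np.array(
            [
                (result.per_or[o]["mean_abs_error"],
                 result.control_per_or[o]["mean_abs_error"])
                for o in actual.index
            ]
        )
        result.comparison_p_error = sign_rank_test(errs[:, 0] - errs[:, 1]).p_value
    return result


def predict_or_responses(
    descriptors: pd.DataFrame,
    responses: pd.DataFrame,
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
    arch: tuple[int, ...] = DEFAULT_ARCH,
    seed: int = 0,
    var_min: float = 0.005,
    corr_max: float = 0.95,
    **train_kwargs,
) -> PredictionResult:
    """End-to-end descriptor -> response pipeline for a panel of ORs.

    ``descriptors`` is odorant x descriptor (missing entries allowed;
    the filter removes them); ``responses`` is OR x odorant.  One
    network is trained per OR on a shared split; the shuffled-matrix
    control is evaluated on the same test odorants.
    """
    odorants = [o for o in responses.columns if o in descriptors.index]
    filtered = filter_descriptors(descriptors.loc[odorants], var_min, corr_max)
    train, val, test = split_odorants(odorants, fractions, seed=seed)
    X_train = filtered.loc[train].to_numpy(float)
    X_val = filtered.loc[val].to_numpy(float)
    X_test = filtered.loc[test].to_numpy(float)
    control = control_predictions(responses[odorants], seed=seed)
    predicted = {}
    for i, or_name in enumerate(responses.index):
        model = train_or_model(
            X_train, responses.loc[or_name, train].to_numpy(float),
            X_val, responses.loc[or_name, val].to_numpy(float),
            arch=arch, seed=seed + i, **train_kwargs,
        )
        predicted[or_name] = model.predict(X_test)
    predicted = pd.DataFrame.from_dict(predicted, orient="index", columns=test)
    return evaluate_predictions(
        predicted, control[test], responses[test], split_seed=seed
    )
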