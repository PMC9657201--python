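"""Gender-specific regression models for total and abdominal fat mass.

The predictors are the dimensionless silhouette features only; body
weight is excluded by contract (it is never accepted as a feature), and
stature is an optional, off-by-default covariate. Ordinary least squares
is the model family: it is the minimal family consistent with the
validation battery's linearity null (slope 1, intercept 0) and it makes
parameter recovery on synthetic cohorts exactly testable. An optional
ridge penalty is available for ill-conditioned feature sets.
"""
from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .errors import (
    CollinearityError,
    ContractError,
    InvalidArgumentError,
    ModelFileError,
    SampleSizeError,
)
from .geometry import FEATURE_ORDER, FeatureVector

__all__ = ["BodyCompModel", "train", "predict", "predict_many", "save_model", "load_model"]

SCHEMA_VERSION = 1
TARGETS = ("fm_total", "fm_abdominal")
FORBIDDEN_FEATURES = ("weight_kg", "weight", "body_weight")


@dataclass(frozen=True)
class BodyCompModel:
    target: str
    gender: str
    feature_names: tuple[str, ...]
    coefficients: dict[str, float]  # kg per unit feature
    intercept: float  # kg
    use_stature: bool
    training_n: int
    training_see: float  # kg, residual SD
    prediction_floor: float = 0.5  # kg

    def __post_init__(self):
        if self.target not in TARGETS:
            raise InvalidArgumentError(f"unknown target {self.target!r}")
        for name in self.feature_names:
            if name in FORBIDDEN_FEATURES:
                raise ContractError("body weight is not an admissible predictor")
        if self.training_see < 0:
            raise InvalidArgumentError("training_see must be non-negative")
        if self.training_n < len(self.feature_names) + 1:
            raise InvalidArgumentError("training_n below parameter count + 1")


def _design(
    fvs: list[FeatureVector], use_stature: bool
) -> tuple[np.ndarray, tuple[str, ...]]:
    names = list(FEATURE_ORDER) + (["stature_cm"] if use_stature else [])
    X = np.vstack([fv.as_array(use_stature) for fv in fvs])
    return X, tuple(names)


def train(
    features: list[FeatureVector],
    reference: np.ndarray,
    target: str,
    gender: str,
    use_stature: bool = False,
    ridge: float = 0.0,
    extra_features: dict[str, np.ndarray] | None = None,
    prediction_floor: float = 0.5,
) -> BodyCompModel:
    """Fit reference fat mass [kg] on the silhouette features by OLS.

    ``extra_features`` may add named columns; any body-weight column is
    refused before fitting. Raises on mixed genders, non-positive
    reference values, too-small samples, or a rank-deficient design.
    """
    if target not in TARGETS:
        raise InvalidArgumentError(f"target must be one of {TARGETS}")
    for fv in features:
        if fv.gender != gender:
            raise ContractError(
                f"training cohort contains {fv.gender!r} records for a {gender!r} model"
            )
    y = np.asarray(reference, dtype=float)
    if y.shape[0] != len(features):
        raise InvalidArgumentError("features and reference lengths differ")
    if not np.all(np.isfinite(y)) or np.any(y <= 0):
        raise InvalidArgumentError("reference values must be finite and positive")

    X, names = _design(features, use_stature)
    if extra_features:
        for name in extra_features:
            if name in FORBIDDEN_FEATURES:
                raise ContractError(
                    f"feature {name!r} refused: body weight is excluded by design"
                )
        names = names + tuple(extra_features)
        X = np.hstack([X] + [np.asarray(v, float).reshape(-1, 1)
                             for v in extra_features.values()])
    if not np.all(np.isfinite(X)):
        raise InvalidArgumentError("non-finite feature values")

    n, p = X.shape
    if n < 2 * (p + 1):
        raise SampleSizeError(f"need at least {2 * (p + 1)} records, got {n}")

    A = np.hstack([np.ones((n, 1)), X])
    rank = np.linalg.matrix_rank(A)
    if rank < p + 1:
        _, _, piv = linalg.qr(A, pivoting=True)
        dropped = [piv[i] for i in range(rank, p + 1)]
        offending = sorted(
            ("intercept" if j == 0 else names[j - 1]) for j in dropped
        )
        raise CollinearityError(
            f"rank-deficient design (rank {rank} < {p + 1}); "
            f"offending features: {offending}",
            features=offending,
        )

    if ridge > 0.0:
        # penalise slopes only, never the intercept
        P = np.eye(p + 1)
        P[0, 0] = 0.0
        beta = np.linalg.solve(A.T @ A + ridge * P, A.T @ y)
    else:
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    dof = n - p - 1
    see = float(np.sqrt(resid @ resid / dof)) if dof > 0 else 0.0
    return BodyCompModel(
        target=target,
        gender=gender,
        feature_names=names,
        coefficients={name: float(b) for name, b in zip(names, beta[1:])},
        intercept=float(beta[0]),
        use_stature=use_stature,
        training_n=n,
        training_see=see,
        prediction_floor=prediction_floor,
    )


def _feature_value(model: BodyCompModel, fv: FeatureVector, name: str) -> float:
    if name == "stature_cm":
        if fv.stature_cm is None:
            raise ContractError("model requires stature but the record has none")
        return fv.stature_cm
    if not hasattr(fv, name):
        raise ContractError(f"feature {name!r} missing from the record")
    return getattr(fv, name)


def predict(model: BodyCompModel, fv: FeatureVector) -> float:
    """Predicted fat mass [kg], floored at the model's plausibility minimum."""
    value, _ = predict_detailed(model, fv)
    return value


def predict_detailed(model: BodyCompModel, fv: FeatureVector) -> tuple[float, bool]:
    """(prediction [kg], was_floored). Pure function of (model, features)."""
    if fv.gender != model.gender:
        raise ContractError(
            f"cannot apply a {model.gender!r} model to a {fv.gender!r} record"
        )
    y = model.intercept + sum(
        model.coefficients[name] * _feature_value(model, fv, name)
        for name in model.feature_names
    )
    if y < model.prediction_floor:
        return model.prediction_floor, True
    return float(y), False


def predict_many(
    model: BodyCompModel, features: list[FeatureVector]
) -> tuple[np.ndarray, np.ndarray]:
    """Vector of predictions and the matching floor flags."""
    pairs = [predict_detailed(model, fv) for fv in features]
    return (
        np.array([p[0] for p in pairs]),
        np.array([p[1] for p in pairs], dtype=bool),
    )


def save_model(model: BodyCompModel, path) -> None:
    payload = {
        "schema_version": SCHEMA_VERSION,
        "target": model.target,
        "gender": model.gender,
        "feature_names": list(model.feature_names),
        "coefficients": model.coefficients,
        "intercept": model.intercept,
        "use_stature": model.use_stature,
        "training_n": model.training_n,
        "training_see": model.training_see,
        "prediction_floor": model.prediction_floor,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)


def load_model(path) -> BodyCompModel:
    try:
        with open(path) as fh:
            d = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ModelFileError(f"malformed model file: {exc}") from exc
    if not isinstance(d, dict) or "schema_version" not in d:
        raise ModelFileError("model file lacks a schema_version")
    if d["schema_version"] != SCHEMA_VERSION:
        raise ModelFileError(
            f"unsupported schema_version {d['schema_version']} "
            f"(this package reads version {SCHEMA_VERSION})"
        )
    try:
        return BodyCompModel(
            target=d["target"],
            gender=d["gender"],
            feature_names=tuple(d["feature_names"]),
            coefficients={k: float(v) for k, v in d["coefficients"].items()},
            intercept=float(d["intercept"]),
            use_stature=bool(d.get("use_stature", False)),
            training_n=int(d["training_n"]),
            training_see=float(d["training_see"]),
            prediction_floor=float(d.get("prediction_floor", 0.5)),
        )
    except KeyError as exc:
        raise ModelFileError(f"model file missing field {exc}") from exc
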