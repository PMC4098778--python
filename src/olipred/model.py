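"""Per-protein linear support-vector classification.

One model is trained per RNA-binding protein.  Training runs a grid search
over the penalty C: for each candidate, an inner stratified cross-validation
on the (already SMOTE-balanced) training data estimates the mean Matthews
correlation coefficient, and the C with the highest mean MCC wins (ties go
to the smallest C).  The final classifier is refit on all training data at
the winning C.  Only the linear kernel is used — balancing happens in the
input space, so the kernel feature space must be the input space.

Scores on [0, 1] come from a Platt-style logistic calibration fit on the
inner-CV decision values; the label is +1 iff score >= 0.5.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import matthews_corrcoef
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC

from .encoding import FeatureSchema, get_schema
from .exceptions import ModelVersionError, SchemaMismatchError, TrainingError

MODEL_FORMAT_VERSION = 1

#: Conventional coarse liblinear-guide grid spanning 2^-5 .. 2^15.
DEFAULT_C_VALUES = tuple(2.0 ** e for e in range(-5, 16, 4))


@dataclass
class GridSpec:
    c_values: tuple[float, ...] = DEFAULT_C_VALUES
    inner_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.c_values or any(c <= 0 for c in self.c_values):
            raise TrainingError("c_values must be non-empty and strictly positive")


@dataclass
class TrainedModel:
    """Linear decision function w.x + b with logistic score calibration."""

    protein: str
    schema: FeatureSchema
    weights: np.ndarray
    bias: float
    C: float
    calibration: tuple[float, float]  # (slope, intercept) on decision values
    training_meta: dict = field(default_factory=dict)

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        X = _check_features(self, X)
        return X @ self.weights + self.bias

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TrainedModel):
            return NotImplemented
        return (
            self.protein == other.protein
            and self.schema == other.schema
            and np.array_equal(self.weights, other.weights)
            and self.bias == other.bias
            and self.C == other.C
            and self.calibration == other.calibration
        )


def _check_features(model: TrainedModel, X) -> np.ndarray:
    if hasattr(X, "columns"):  # DataFrame: verify column order too
        if tuple(X.columns) != model.schema.feature_names:
            raise SchemaMismatchError(
                f"feature columns do not match schema {model.schema.name!r}"
            )
        X = X.to_numpy()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.schema.dim:
        raise SchemaMismatchError(
            f"feature matrix has {X.shape[1]} columns; schema "
            f"{model.schema.name!r} expects {model.schema.dim}"
        )
    return X


def _fit_svc(X: np.ndarray, y: np.ndarray, C: float) -> LinearSVC:
    # primal Newton solver: deterministic and well-converged across the wide
    # C grid; the iteration cap only bites at the extreme C values, where the
    # inner-CV MCC is measured on whatever the capped fit produces
    clf = LinearSVC(C=C, dual=False, max_iter=1000, random_state=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(X, y)
    return clf


def train(
    X: np.ndarray,
    y: np.ndarray,
    grid: GridSpec | None = None,
    protein: str = "",
    schema: FeatureSchema | str = "oli",
    ids: Sequence[str] | None = None,
) -> TrainedModel:
    """Grid-search C by inner-CV mean MCC, refit at the winner, calibrate.

    *X*, *y* are the (balanced) training fold.  Raises on single-class input
    and on non-finite features (naming the offending sequence when ids are
    supplied).
    """
    if grid is None:
        grid = GridSpec()
    if isinstance(schema, str):
        schema = get_schema(schema)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    classes = np.unique(y)
    if len(classes) < 2:
        raise TrainingError(f"training data contains a single class: {classes}")
    bad_rows = np.where(~np.isfinite(X).all(axis=1))[0]
    if bad_rows.size:
        name = ids[bad_rows[0]] if ids is not None else f"row {bad_rows[0]}"
        raise TrainingError(f"non-finite feature value in {name}")
    if X.shape[1] != schema.dim:
        raise SchemaMismatchError(
            f"feature matrix has {X.shape[1]} columns; schema "
            f"{schema.name!r} expects {schema.dim}"
        )

    minority = int(np.min(np.bincount((y == 1).astype(int))))
    if minority < 2:
        raise TrainingError("need at least 2 samples of each class for inner CV")
    n_splits = max(2, min(grid.inner_folds, minority))
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=grid.seed)
    folds = list(skf.split(X, y))

    mean_mcc: dict[float, float] = {}
    for C in grid.c_values:
        mccs = []
        for tr, va in folds:
            clf = _fit_svc(X[tr], y[tr], C)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                mccs.append(matthews_corrcoef(y[va], clf.predict(X[va])))
        mean_mcc[C] = float(np.mean(mccs))
    # highest mean MCC wins; scanning ascending C with strict '>' breaks ties
    # toward the smallest C
    best_C, best = None, -np.inf
    for C in sorted(grid.c_values):
        if mean_mcc[C] > best + 1e-12:
            best_C, best = C, mean_mcc[C]
    assert best_C is not None

    # Platt-style calibration on out-of-fold decision values at the winner
    oof_dec = np.empty(len(y))
    for tr, va in folds:
        clf = _fit_svc(X[tr], y[tr], best_C)
        oof_dec[va] = clf.decision_function(X[va])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        platt = LogisticRegression(C=1e6)
        platt.fit(oof_dec[:, None], y)
    # orient to the +1 class
    pos_col = int(np.where(platt.classes_ == +1)[0][0])
    sign = 1.0 if pos_col == 1 else -1.0
    slope = sign * float(platt.coef_[0, 0])
    intercept = sign * float(platt.intercept_[0])

    final = _fit_svc(X, y, best_C)
    w = final.coef_[0].astype(float)
    b = float(final.intercept_[0])
    if final.classes_[1] != +1:  # orient decision values toward +1
        w, b = -w, -b
        slope = -slope  # calibration was fit on +1-oriented values; keep consistent

    return TrainedModel(
        protein=protein,
        schema=schema,
        weights=w,
        bias=b,
        C=best_C,
        calibration=(slope, intercept),
        training_meta={
            "seed": grid.seed,
            "inner_folds": n_splits,
            "grid_mean_mcc": {f"{c:g}": mean_mcc[c] for c in grid.c_values},
            "schema_version": schema.version,
        },
    )


def predict(model: TrainedModel, X) -> tuple[np.ndarray, np.ndarray]:
    """Calibrated scores in [0, 1] and hard labels (+1 iff score >= 0.5)."""
    dec = model.decision_values(X)
    slope, intercept = model.calibration
    scores = 1.0 / (1.0 + np.exp(-(slope * dec + intercept)))
    labels = np.where(scores >= 0.5, +1, -1)
    return scores, labels


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Versioned flat JSON serialization (lossless round-trip)."""
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "protein": model.protein,
        "schema_name": model.schema.name,
        "schema_version": model.schema.version,
        "weights": model.weights.tolist(),
        "bias": model.bias,
        "C": model.C,
        "calibration": list(model.calibration),
        "training_meta": model.training_meta,
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> TrainedModel:
    payload = json.loads(Path(path).read_text())
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ModelVersionError(
            f"model format version {payload.get('format_version')!r} is not "
            f"supported (expected {MODEL_FORMAT_VERSION})"
        )
    schema = get_schema(payload["schema_name"])
    if payload.get("schema_version") != schema.version:
        raise ModelVersionError(
            f"model was saved under feature-schema version "
            f"{payload.get('schema_version')!r} but the current "
            f"{schema.name!r} schema is {schema.version!r}"
        )
    return TrainedModel(
        protein=payload["protein"],
        schema=schema,
        weights=np.array(payload["weights"], dtype=float),
        bias=float(payload["bias"]),
        C=float(payload["C"]),
        calibration=tuple(payload["calibration"]),
        training_meta=payload.get("training_meta", {}),
    )
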