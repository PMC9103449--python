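"""Surrogate models: a gradient-boosted-tree regressor plus two baselines.

The primary surrogate is XGBoost with squared-error objective and L2 leaf
regularization, pinned to a minimal deterministic configuration (exact tree
method, no row/column subsampling, min child weight 1, single thread). The
shipped hyperparameters are the tuned operating point for the augmented
tensile-stress benchmark: 55 trees, learning rate 0.16, max depth 8,
reg_lambda 120.

Hyperparameters can be re-derived with :func:`tune`, a coordinate-wise
learning-curve search: each parameter is swept over a grid with the others
held fixed, scoring by mean 10-fold cross-validated R^2, in the fixed order
n_trees -> eta -> max_depth -> reg_lambda. The same fold seed is used for the
whole sweep so scores along a curve are comparable.

Baselines: ordinary least squares (``mlr``) and RBF-kernel support-vector
regression on standardized features (``svr``, C=1, epsilon=0.1,
gamma='scale' i.e. 1/(d * Var(X))).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import xgboost as xgb
import yaml
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import KFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .data import FeatureTable
from .errors import FoldSizeError, InvalidSpecError, MissingTargetError
from .evaluation import r2
from .seeding import stage_seed

MODEL_KINDS = ("gbt", "mlr", "svr")

#: coordinate order of the learning-curve sweep
TUNE_ORDER = ("n_trees", "eta", "max_depth", "reg_lambda")


@dataclass
class SurrogateSpec:
    """Boosted-tree hyperparameters (all other knobs pinned to the minimal
    deterministic configuration)."""

    n_trees: int = 55
    eta: float = 0.16
    max_depth: int = 8
    reg_lambda: float = 120.0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise InvalidSpecError("n_trees must be >= 1")
        if not (0 < self.eta <= 1):
            raise InvalidSpecError("eta must be in (0, 1]")
        if self.max_depth < 1:
            raise InvalidSpecError("max_depth must be >= 1")
        if self.reg_lambda < 0:
            raise InvalidSpecError("reg_lambda must be >= 0")


@dataclass
class Model:
    """A fitted predictor plus its training metadata."""

    kind: str
    predictor: object
    feature_names: tuple[str, ...]
    spec: SurrogateSpec | None = None
    seed: int = 0
    n_train: int = 0
    train_min: np.ndarray | None = None
    train_max: np.ndarray | None = None

    def predict(self, X) -> np.ndarray:
        """Predict tensile stress for an (n, d) matrix, DataFrame (columns
        matched by name) or FeatureTable."""
        if isinstance(X, FeatureTable):
            if X.feature_names != self.feature_names:
                raise InvalidSpecError(
                    f"feature names {X.feature_names} != {self.feature_names}"
                )
            X = X.X
        elif isinstance(X, pd.DataFrame):
            missing = set(self.feature_names) - set(X.columns)
            if missing:
                raise InvalidSpecError(f"missing feature columns: {sorted(missing)}")
            X = X.loc[:, list(self.feature_names)].to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(self.feature_names):
            raise InvalidSpecError(
                f"expected (n, {len(self.feature_names)}) matrix, got {X.shape}"
            )
        return np.asarray(self.predictor.predict(X), dtype=float).ravel()


def _xgb_regressor(spec: SurrogateSpec, seed: int) -> xgb.XGBRegressor:
    return xgb.XGBRegressor(
        n_estimators=spec.n_trees,
        learning_rate=spec.eta,
        max_depth=spec.max_depth,
        reg_lambda=spec.reg_lambda,
        objective="reg:squarederror",
        tree_method="exact",
        subsample=1.0,
        colsample_bytree=1.0,
        colsample_bylevel=1.0,
        colsample_bynode=1.0,
        min_child_weight=1,
        n_jobs=1,
        random_state=int(seed) % (2**31),
    )


def fit_gbt(
    train: FeatureTable, spec: SurrogateSpec | None = None, seed: int = 0
) -> Model:
    """Fit the gradient-boosted surrogate; deterministic given (data, spec,
    seed)."""
    spec = spec or SurrogateSpec()
    if not train.has_target:
        raise MissingTargetError("fit_gbt requires a target column")
    if train.n < 2:
        raise InvalidSpecError("need n >= 2 to fit")
    reg = _xgb_regressor(spec, stage_seed(seed, "fit"))
    reg.fit(train.X, train.y)
    return Model(
        kind="gbt",
        predictor=reg,
        feature_names=train.feature_names,
        spec=spec,
        seed=seed,
        n_train=train.n,
        train_min=train.X.min(axis=0),
        train_max=train.X.max(axis=0),
    )


def fit_baseline(train: FeatureTable, kind: str, seed: int = 0) -> Model:
    """Fit a comparison baseline: ``mlr`` (OLS with intercept; singular
    designs fall back to the minimum-norm solution via lstsq) or ``svr``
    (RBF-kernel SVR on standardized features)."""
    if not train.has_target:
        raise MissingTargetError("fit_baseline requires a target column")
    if kind == "mlr":
        predictor = LinearRegression().fit(train.X, train.y)
    elif kind == "svr":
        predictor = Pipeline(
            [
                ("scale", StandardScaler()),
                ("svr", SVR(kernel="rbf", C=1.0, epsilon=0.1, gamma="scale")),
            ]
        ).fit(train.X, train.y)
    else:
        raise InvalidSpecError(f"unknown baseline kind {kind!r}")
    return Model(
        kind=kind,
        predictor=predictor,
        feature_names=train.feature_names,
        seed=seed,
        n_train=train.n,
        train_min=train.X.min(axis=0),
        train_max=train.X.max(axis=0),
    )


def fit_model(
    train: FeatureTable,
    kind: str = "gbt",
    spec: SurrogateSpec | None = None,
    seed: int = 0,
) -> Model:
    """Dispatch on *kind* (gbt | mlr | svr)."""
    if kind == "gbt":
        return fit_gbt(train, spec, seed)
    return fit_baseline(train, kind, seed)


def cv_score(
    table: FeatureTable,
    spec: SurrogateSpec | None = None,
    folds: int = 10,
    seed: int = 0,
    kind: str = "gbt",
) -> float:
    """Mean held-out R^2 over a shuffled K-fold partition.

    Every test fold must contain at least two rows (R^2 is undefined on a
    singleton), so leave-one-out is rejected.
    """
    if folds < 2:
        raise InvalidSpecError("folds must be >= 2")
    if table.n < folds:
        raise FoldSizeError(f"n={table.n} < folds={folds}")
    if table.n // folds < 2:
        raise FoldSizeError(
            f"folds={folds} would give test folds of size {table.n // folds}; "
            "minimum test-fold size is 2"
        )
    kf = KFold(n_splits=folds, shuffle=True, random_state=int(seed) % (2**31))
    scores = []
    for train_idx, test_idx in kf.split(table.X):
        model = fit_model(table.subset(train_idx), kind=kind, spec=spec, seed=seed)
        scores.append(r2(table.y[test_idx], model.predict(table.X[test_idx])))
    return float(np.mean(scores))


def paper_grids() -> dict[str, list]:
    """The full learning-curve grids: trees 1..100, eta 0.10..0.30 by 0.01,
    depth 3..15, reg_lambda {0, 1, 10, 60, 120, 240}."""
    return {
        "n_trees": list(range(1, 101)),
        "eta": [round(0.10 + 0.01 * i, 2) for i in range(21)],
        "max_depth": list(range(3, 16)),
        "reg_lambda": [0.0, 1.0, 10.0, 60.0, 120.0, 240.0],
    }


def tune(
    table: FeatureTable,
    grids: dict[str, Sequence] | None = None,
    seed: int = 0,
    folds: int = 10,
    start: SurrogateSpec | None = None,
) -> tuple[SurrogateSpec, list[tuple[str, float, float]]]:
    """Coordinate-wise greedy learning-curve search.

    Sweeps each parameter in :data:`TUNE_ORDER` over its grid with the others
    held at their current values, keeping the argmax of :func:`cv_score`
    (ties broken toward the smaller, more regular value by sweeping the grid
    in ascending order with a strict improvement test). Returns the tuned
    spec and the full (parameter, value, score) trace.
    """
    grids = grids if grids is not None else paper_grids()
    if not grids or any(len(g) == 0 for g in grids.values()):
        raise InvalidSpecError("grids must be non-empty")
    unknown = set(grids) - set(TUNE_ORDER)
    if unknown:
        raise InvalidSpecError(f"unknown tuning parameters: {sorted(unknown)}")
    current = start or SurrogateSpec()
    fold_seed = stage_seed(seed, "tune")  # shared across the whole sweep
    trace: list[tuple[str, float, float]] = []
    for param in TUNE_ORDER:
        if param not in grids:
            continue
        best_val, best_score = None, -np.inf
        for val in sorted(grids[param]):
            candidate = replace(current, **{param: val})
            score = cv_score(table, candidate, folds=folds, seed=fold_seed)
            trace.append((param, float(val), score))
            if score > best_score:
                best_val, best_score = val, score
        current = replace(current, **{param: best_val})
    return current, trace


# -- persistence -----------------------------------------------------------

class _BoosterPredictor:
    """Predict shim for a bare xgboost Booster loaded from its JSON dump."""

    def __init__(self, booster: xgb.Booster):
        self.booster = booster

    def predict(self, X) -> np.ndarray:
        return self.booster.predict(xgb.DMatrix(np.asarray(X, dtype=float)))


def save_model(model: Model, path: str | Path) -> None:
    """Serialize a fitted model to text files.

    ``gbt`` writes the booster's JSON next to a ``<path>.meta.yaml`` sidecar;
    ``mlr`` writes coefficients into the sidecar alone. ``svr`` has no
    portable text form here and refitting is cheap, so it is rejected.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {
        "kind": model.kind,
        "feature_names": list(model.feature_names),
        "seed": int(model.seed),
        "n_train": int(model.n_train),
        "train_min": None if model.train_min is None else model.train_min.tolist(),
        "train_max": None if model.train_max is None else model.train_max.tolist(),
    }
    if model.kind == "gbt":
        assert model.spec is not None
        meta["spec"] = {
            "n_trees": model.spec.n_trees,
            "eta": model.spec.eta,
            "max_depth": model.spec.max_depth,
            "reg_lambda": model.spec.reg_lambda,
        }
        model.predictor.get_booster().save_model(str(path))
    elif model.kind == "mlr":
        meta["coef"] = np.asarray(model.predictor.coef_).tolist()
        meta["intercept"] = float(model.predictor.intercept_)
    else:
        raise InvalidSpecError("svr models are refit in-session, not persisted")
    with open(f"{path}.meta.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(meta, fh)


def load_model(path: str | Path) -> Model:
    """Inverse of :func:`save_model`."""
    path = Path(path)
    with open(f"{path}.meta.yaml", encoding="utf-8") as fh:
        meta = yaml.safe_load(fh)
    kind = meta["kind"]
    if kind == "gbt":
        booster = xgb.Booster()
        booster.load_model(str(path))
        predictor = _BoosterPredictor(booster)
        spec = SurrogateSpec(**meta["spec"])
    elif kind == "mlr":
        predictor = LinearRegression()
        predictor.coef_ = np.asarray(meta["coef"], dtype=float)
        predictor.intercept_ = float(meta["intercept"])
        spec = None
    else:
        raise InvalidSpecError(f"cannot load model kind {kind!r}")
    return Model(
        kind=kind,
        predictor=predictor,
        feature_names=tuple(meta["feature_names"]),
        spec=spec,
        seed=meta["seed"],
        n_train=meta["n_train"],
        train_min=None if meta["train_min"] is None else np.asarray(meta["train_min"]),
        train_max=None if meta["train_max"] is None else np.asarray(meta["train_max"]),
    )
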