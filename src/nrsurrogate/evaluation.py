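"""Performance metrics and the repeated-random-split robustness protocol.

Two metrics:

* the coefficient of determination
  ``R^2 = 1 - sum (X_i - Xhat_i)^2 / sum (X_i - Xbar)^2``;
* coverage, the fraction of predictions whose absolute error is within twice
  the standard deviation of the absolute observed values::

      Cov = (1/N) sum h( |X_i - Xhat_i| / (2 * sd(|X_i|)) ),
      h(x) = 1 if x <= 1 else 0

  (the boundary, error exactly equal to 2*sd, counts as covered). sd uses
  the N-1 denominator and is computed over the evaluation set.

The robustness protocol draws many independent random train/test splits
(default 999), refits each candidate model on every training part, and
reports the full per-split R^2/Cov vectors plus min/mean/max summaries.
Splits operate on the supplied table as-is — augmentation is not re-run per
split. A ``test_originals_only`` mode restricts the test pool to
original-provenance rows, guarding against the optimism of scoring on
synthetic neighbors of training rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .data import FeatureTable
from .errors import ConstantTargetError, InvalidSpecError, ZeroSpreadError
from .seeding import child_seed


def r2(y: np.ndarray, yhat: np.ndarray) -> float:
    """Coefficient of determination; may be negative for bad models."""
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.shape != yhat.shape:
        raise InvalidSpecError("y and yhat must have equal length")
    if y.size < 2:
        raise InvalidSpecError("need N >= 2")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ConstantTargetError("R^2 undefined: observed values are constant")
    ss_res = float(np.sum((y - yhat) ** 2))
    return 1.0 - ss_res / ss_tot


def coverage(y: np.ndarray, yhat: np.ndarray) -> float:
    """Fraction of predictions with |error| <= 2*sd(|y|); in [0, 1]."""
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.shape != yhat.shape:
        raise InvalidSpecError("y and yhat must have equal length")
    if y.size < 2:
        raise InvalidSpecError("need N >= 2")
    sd_abs = float(np.std(np.abs(y), ddof=1))
    if sd_abs == 0:
        raise ZeroSpreadError("coverage undefined: sd(|y|) is zero")
    ratio = np.abs(y - yhat) / (2.0 * sd_abs)
    return float(np.mean(ratio <= 1.0))


@dataclass
class EvalSpec:
    """Robustness-protocol settings."""

    n_splits: int = 999
    test_fraction: float = 0.1
    test_originals_only: bool = False

    def __post_init__(self) -> None:
        if self.n_splits < 1:
            raise InvalidSpecError("n_splits must be >= 1")
        if not (0 < self.test_fraction < 1):
            raise InvalidSpecError("test_fraction must be in (0, 1)")


@dataclass
class EvaluationReport:
    """Per-split metric vectors for each model plus consistency helpers."""

    r2_values: dict[str, np.ndarray]
    cov_values: dict[str, np.ndarray]
    spec: EvalSpec = field(default_factory=EvalSpec)

    @property
    def model_names(self) -> list[str]:
        return list(self.r2_values)

    def summary(self) -> dict[str, dict[str, dict[str, float]]]:
        """{model: {metric: {min, mean, max}}} recomputed from the vectors."""
        out: dict[str, dict[str, dict[str, float]]] = {}
        for name in self.model_names:
            out[name] = {}
            for metric, vec in (("r2", self.r2_values[name]),
                                ("cov", self.cov_values[name])):
                out[name][metric] = {
                    "min": float(np.min(vec)),
                    "mean": float(np.mean(vec)),
                    "max": float(np.max(vec)),
                }
        return out

    def to_frame(self) -> pd.DataFrame:
        """One row per split, columns ``<model>_r2`` / ``<model>_cov``."""
        cols = {}
        for name in self.model_names:
            cols[f"{name}_r2"] = self.r2_values[name]
            cols[f"{name}_cov"] = self.cov_values[name]
        df = pd.DataFrame(cols)
        df.insert(0, "split", np.arange(len(df)))
        return df

    def summary_text(self) -> str:
        lines = []
        for name, metrics in self.summary().items():
            for metric, s in metrics.items():
                lines.append(
                    f"{name:>8s}  {metric:<4s} min={s['min']:.3f} "
                    f"mean={s['mean']:.3f} max={s['max']:.3f}"
                )
        return "\n".join(lines)


ModelFitter = Callable[[FeatureTable, int], object]


def split_indices(
    table: FeatureTable, spec: EvalSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """One random (train, test) split. The test pool is the whole table, or
    only original rows under ``test_originals_only``; training gets every row
    not in the test set."""
    pool = (
        np.flatnonzero(table.original_mask())
        if spec.test_originals_only
        else np.arange(table.n)
    )
    n_test = max(2, int(round(spec.test_fraction * pool.size)))
    if n_test >= pool.size or table.n - n_test < 2:
        raise InvalidSpecError("table too small for the requested split")
    test = rng.choice(pool, size=n_test, replace=False)
    test_mask = np.zeros(table.n, dtype=bool)
    test_mask[test] = True
    return np.flatnonzero(~test_mask), np.sort(test)


def robustness(
    table: FeatureTable,
    fitters: Mapping[str, ModelFitter],
    spec: EvalSpec | None = None,
    seed: int = 0,
) -> EvaluationReport:
    """Repeated-random-split evaluation of one or more models.

    *fitters* maps a model name to ``fit(train_table, seed) -> model`` where
    the returned object has ``predict(X) -> yhat``. Each split s uses an
    independent child seed of *seed*, so the protocol is reproducible and
    individual splits can be re-drawn in isolation.
    """
    spec = spec or EvalSpec()
    if not table.has_target:
        raise InvalidSpecError("robustness evaluation requires targets")
    r2_vals = {name: np.empty(spec.n_splits) for name in fitters}
    cov_vals = {name: np.empty(spec.n_splits) for name in fitters}
    for s in range(spec.n_splits):
        split_rng = np.random.default_rng(child_seed(seed, s))
        train_idx, test_idx = split_indices(table, spec, split_rng)
        train = table.subset(train_idx)
        test = table.subset(test_idx)
        for name, fit in fitters.items():
            model = fit(train, child_seed(seed, s))
            yhat = model.predict(test.X)
            r2_vals[name][s] = r2(test.y, yhat)
            cov_vals[name][s] = coverage(test.y, yhat)
    return EvaluationReport(r2_values=r2_vals, cov_values=cov_vals, spec=spec)
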