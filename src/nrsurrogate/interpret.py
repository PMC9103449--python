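"""Exact Shapley attribution and response-surface prediction.

With only three features, Shapley values are computed exactly by enumerating
all 2^d coalitions with the interventional (marginal-expectation) value
function::

    v(S) = mean over background rows b of f(x_S joined with b_{~S})
    phi_j = sum over S not containing j of
            |S|! (d - |S| - 1)! / d! * (v(S + {j}) - v(S))

This is the quantity sampling-based SHAP explainers estimate, computed
without approximation — affordable because 2^3 = 8 coalitions — and it
satisfies local accuracy exactly: base value + sum_j phi_j equals the model
prediction at each explained row.

Global importance is the mean absolute attribution per feature over a table,
and the response surface evaluates the surrogate on a dense
(eps_h, omega) grid at a fixed eps_nh slice (default 0.38 kcal/mol, the
force field's background interaction strength).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .data import FeatureTable
from .errors import InvalidSpecError
from .models import Model

#: enumeration guard — 2^d coalitions, each a full background sweep
MAX_EXACT_FEATURES = 12


@dataclass
class AttributionReport:
    """Per-row Shapley values (MPa) against a background expectation."""

    phi: np.ndarray  # (n, d)
    base_value: float
    feature_names: tuple[str, ...]
    predictions: np.ndarray  # (n,) model output at each explained row

    def mean_abs(self) -> np.ndarray:
        return np.abs(self.phi).mean(axis=0)

    def ranking(self) -> list[tuple[str, float]]:
        """Features by descending mean |phi|; ties keep column order."""
        vals = self.mean_abs()
        order = sorted(range(len(vals)), key=lambda j: (-vals[j], j))
        return [(self.feature_names[j], float(vals[j])) for j in order]

    def local_accuracy_error(self) -> float:
        """max |base + sum_j phi_ij - f(x_i)| over explained rows."""
        return float(
            np.max(np.abs(self.base_value + self.phi.sum(axis=1) - self.predictions))
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.phi, columns=[f"phi_{f}" for f in self.feature_names])
        df["prediction"] = self.predictions
        df["base_value"] = self.base_value
        return df


def _coalition_values(
    predict: Callable[[np.ndarray], np.ndarray],
    background: np.ndarray,
    X: np.ndarray,
) -> np.ndarray:
    """v[i, mask] = mean_b f(background row b with mask-features from X[i]);
    vectorized over explained rows and background."""
    n, d = X.shape
    m = background.shape[0]
    v = np.empty((n, 2**d))
    tiled = np.tile(background, (n, 1))
    for mask in range(2**d):
        Z = tiled.copy()
        for j in range(d):
            if mask >> j & 1:
                Z[:, j] = np.repeat(X[:, j], m)
        v[:, mask] = np.asarray(predict(Z), dtype=float).reshape(n, m).mean(axis=1)
    return v


def shapley_values(
    predict: Callable[[np.ndarray], np.ndarray],
    background: np.ndarray | FeatureTable,
    X: np.ndarray,
) -> tuple[np.ndarray, float]:
    """Exact interventional Shapley values for every row of X.

    Returns (phi, base_value) where phi is (n, d) and base_value is the mean
    background prediction v(empty set).
    """
    if isinstance(background, FeatureTable):
        background = background.X
    background = np.asarray(background, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if background.size == 0:
        raise InvalidSpecError("background must be non-empty")
    d = X.shape[1]
    if d > MAX_EXACT_FEATURES:
        raise InvalidSpecError(
            f"exact enumeration guarded at d <= {MAX_EXACT_FEATURES}, got d={d}"
        )
    v = _coalition_values(predict, background, X)
    fact = [math.factorial(i) for i in range(d + 1)]
    phi = np.zeros((X.shape[0], d))
    for mask in range(2**d):
        s = bin(mask).count("1")
        w = fact[s] * fact[d - s - 1] / fact[d]
        for j in range(d):
            if not mask >> j & 1:
                phi[:, j] += w * (v[:, mask | (1 << j)] - v[:, mask])
    return phi, float(v[0, 0])


def exact_shapley(
    predict: Callable[[np.ndarray], np.ndarray],
    background: np.ndarray | FeatureTable,
    x: np.ndarray,
) -> np.ndarray:
    """Shapley attribution vector for a single feature row."""
    phi, _ = shapley_values(predict, background, np.atleast_2d(x))
    return phi[0]


def explain_table(
    model: Model,
    table: FeatureTable,
    background: FeatureTable | None = None,
    max_background: int = 256,
    seed: int = 0,
) -> AttributionReport:
    """Attribute every row of *table*, using the table itself as background
    (subsampled without replacement beyond *max_background* rows for speed).
    """
    if table.n < 1:
        raise InvalidSpecError("need at least one row to explain")
    bg = (background or table).X
    if bg.shape[0] > max_background:
        rng = np.random.default_rng(int(seed) % (2**31))
        bg = bg[rng.choice(bg.shape[0], size=max_background, replace=False)]
    phi, base = shapley_values(model.predict, bg, table.X)
    return AttributionReport(
        phi=phi,
        base_value=base,
        feature_names=table.feature_names,
        predictions=model.predict(table.X),
    )


def importance_ranking(
    model: Model,
    table: FeatureTable,
    max_background: int = 256,
    seed: int = 0,
) -> list[tuple[str, float]]:
    """Global importance: features ordered by mean |Shapley value| over the
    table."""
    return explain_table(model, table, max_background=max_background,
                         seed=seed).ranking()


@dataclass
class SurfaceGrid:
    """Dense (eps_h, omega) -> TS prediction grid at fixed eps_nh.

    ``ts[i, j]`` is the prediction at ``omega[i]``, ``eps_h[j]``.
    """

    eps_nh_fixed: float
    eps_h: np.ndarray
    omega: np.ndarray
    ts: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.eps_h) <= 0) or np.any(np.diff(self.omega) <= 0):
            raise InvalidSpecError("grid axes must be strictly increasing")
        if self.ts.shape != (self.omega.size, self.eps_h.size):
            raise InvalidSpecError("ts shape must be (len(omega), len(eps_h))")

    def to_frame(self) -> pd.DataFrame:
        """Long format: one (eps_h, omega, ts) row per grid point."""
        ee, ww = np.meshgrid(self.eps_h, self.omega)
        return pd.DataFrame(
            {"eps_h": ee.ravel(), "omega": ww.ravel(), "ts": self.ts.ravel()}
        )


def predict_surface(
    model: Model,
    eps_nh_fixed: float = 0.38,
    eps_h: np.ndarray | tuple[float, float, int] = (0.38, 5.0, 200),
    omega: np.ndarray | tuple[float, float, int] = (0.0, 30.0, 200),
    batch: int = 65536,
) -> SurfaceGrid:
    """Predict tensile stress over a Cartesian (eps_h, omega) grid with
    eps_nh held fixed; deterministic, evaluated in batches.

    Axes may be given as arrays or (low, high, num) tuples. A warning is
    emitted when the grid leaves the model's training envelope.
    """
    eps_h_ax = _axis(eps_h)
    omega_ax = _axis(omega)
    names = model.feature_names
    try:
        j_w, j_h, j_nh = names.index("omega"), names.index("eps_h"), names.index("eps_nh")
    except ValueError as exc:
        raise InvalidSpecError(
            f"surface prediction expects features omega/eps_h/eps_nh, got {names}"
        ) from exc
    if model.train_min is not None:
        lo, hi = model.train_min, model.train_max
        outside = (
            eps_h_ax[0] < lo[j_h] or eps_h_ax[-1] > hi[j_h]
            or omega_ax[0] < lo[j_w] or omega_ax[-1] > hi[j_w]
            or not (lo[j_nh] <= eps_nh_fixed <= hi[j_nh])
        )
        if outside:
            warnings.warn(
                "surface grid extends beyond the training envelope; "
                "tree-based predictions flatten out there",
                stacklevel=2,
            )
    ee, ww = np.meshgrid(eps_h_ax, omega_ax)
    pts = np.empty((ee.size, 3))
    pts[:, j_h] = ee.ravel()
    pts[:, j_w] = ww.ravel()
    pts[:, j_nh] = eps_nh_fixed
    preds = np.concatenate(
        [model.predict(pts[i : i + batch]) for i in range(0, pts.shape[0], batch)]
    )
    return SurfaceGrid(
        eps_nh_fixed=eps_nh_fixed,
        eps_h=eps_h_ax,
        omega=omega_ax,
        ts=preds.reshape(omega_ax.size, eps_h_ax.size),
    )


def _axis(spec) -> np.ndarray:
    if isinstance(spec, tuple) and len(spec) == 3:
        lo, hi, num = spec
        return np.linspace(lo, hi, int(num))
    return np.asarray(spec, dtype=float)
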