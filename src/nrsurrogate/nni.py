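"""Nearest-neighbor-interpolation (NNI) Gaussian augmentation.

Each original sample is surrounded by k synthetic points drawn feature-wise
from a normal distribution centered on the sample::

    x_new_j ~ N(x_ij, sigma2_j),   sigma2_j = (lambda / m) * sum_i x_ij

so the per-feature variance is the interpolation parameter lambda times the
feature's mean over the m original rows. sigma2 is computed once from the
original rows and never updated as synthetics accumulate.

Targets for synthetic rows are not defined by the augmentation rule itself;
two label rules are offered:

* ``inherit_parent`` (default): copy the parent's target — each synthetic
  lives in its parent's neighborhood;
* ``knn_idw``: inverse-distance-weighted mean of the targets of the
  ``knn_k`` nearest original rows in standardized feature space (KD-tree
  accelerated; the parent is eligible and dominates at zero distance).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .data import FeatureTable
from .errors import (
    InvalidSpecError,
    MissingTargetError,
    NegativeFeatureMeanError,
)
from .seeding import stage_rng

LABEL_RULES = ("inherit_parent", "knn_idw")


@dataclass
class AugmentationSpec:
    """Parameters of the NNI stage.

    lambda_ scales the interpolation neighborhood (variance = lambda * feature
    mean); points_per_sample is k, the synthetics per original row.
    clamp_nonnegative optionally floors synthetic features at zero for
    physically nonnegative columns; off by default since the Gaussian rule is
    unbounded.
    """

    lambda_: float = 0.1
    points_per_sample: int = 20
    label_rule: str = "inherit_parent"
    knn_k: int = 3
    clamp_nonnegative: bool = False

    def __post_init__(self) -> None:
        if self.lambda_ < 0:
            raise InvalidSpecError("lambda_ must be >= 0")
        if self.points_per_sample < 0:
            raise InvalidSpecError("points_per_sample must be >= 0")
        if self.label_rule not in LABEL_RULES:
            raise InvalidSpecError(
                f"label_rule must be one of {LABEL_RULES}, got {self.label_rule!r}"
            )
        if self.knn_k < 1:
            raise InvalidSpecError("knn_k must be >= 1")


def feature_variance(table: FeatureTable, lambda_: float) -> np.ndarray:
    """Per-feature interpolation variance sigma2_j = (lambda/m) * sum_i x_ij.

    Computed over the original-provenance rows only. The rule derives a
    variance from a mean, so it presumes nonnegative feature values; a
    negative feature mean raises rather than silently taking an absolute
    value.
    """
    if lambda_ < 0:
        raise InvalidSpecError("lambda_ must be >= 0")
    Xo = table.X[table.original_mask()]
    if Xo.shape[0] < 1:
        raise InvalidSpecError("table has no original rows")
    means = Xo.mean(axis=0)
    if (means < 0).any():
        bad = [table.feature_names[j] for j in np.flatnonzero(means < 0)]
        raise NegativeFeatureMeanError(
            f"negative feature mean(s) for {bad}; the variance rule requires "
            "nonnegative feature values"
        )
    return lambda_ * means


def nni_augment(
    table: FeatureTable, spec: AugmentationSpec | None = None, seed: int = 0
) -> FeatureTable:
    """Augment *table* to m*(k+1) rows: the m originals (bit-exact, first),
    then k Gaussian synthetics per original in parent order, tagged ``nni``.
    """
    spec = spec or AugmentationSpec()
    if not table.has_target:
        raise MissingTargetError("NNI augmentation requires a target column")
    k = spec.points_per_sample
    if k == 0:
        return table.copy()

    mask = table.original_mask()
    originals = table.subset(np.flatnonzero(mask))
    m, d = originals.n, originals.d
    sigma2 = feature_variance(table, spec.lambda_)
    sd = np.sqrt(sigma2)

    rng = stage_rng(seed, "nni")
    centers = np.repeat(originals.X, k, axis=0)  # parent-major order
    synth_X = rng.normal(centers, sd, size=(m * k, d))
    if spec.clamp_nonnegative:
        synth_X = np.maximum(synth_X, 0.0)

    if spec.label_rule == "inherit_parent":
        synth_y = np.repeat(originals.y, k)
    else:
        synth_y = _knn_idw_labels(originals, synth_X, spec.knn_k)

    return FeatureTable(
        X=np.vstack([originals.X, synth_X]),
        feature_names=table.feature_names,
        y=np.concatenate([originals.y, synth_y]),
        provenance=np.concatenate(
            [originals.provenance, np.full(m * k, "nni", dtype=object)]
        ),
    )


def _knn_idw_labels(
    originals: FeatureTable, synth_X: np.ndarray, knn_k: int
) -> np.ndarray:
    """Inverse-distance-weighted target over the knn_k nearest originals in
    z-scored feature space."""
    mu = originals.X.mean(axis=0)
    sigma = originals.X.std(axis=0, ddof=0)
    sigma[sigma == 0] = 1.0  # constant feature: pass through unscaled
    tree = cKDTree((originals.X - mu) / sigma)
    k = min(knn_k, originals.n)
    dist, idx = tree.query((synth_X - mu) / sigma, k=k)
    dist = np.atleast_2d(dist.reshape(synth_X.shape[0], k))
    idx = np.atleast_2d(idx.reshape(synth_X.shape[0], k))
    # exact hits get full weight for the coincident point
    with np.errstate(divide="ignore"):
        w = 1.0 / dist
    exact = np.isinf(w)
    has_exact = exact.any(axis=1)
    w[has_exact] = exact[has_exact].astype(float)
    return (w * originals.y[idx]).sum(axis=1) / w.sum(axis=1)
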