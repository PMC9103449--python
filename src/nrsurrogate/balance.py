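"""Sample-imbalance correction: K-means clustering + Borderline-SMOTE
adapted to regression targets.

Augmented experimental designs are typically concentrated in a few regions of
feature space. The stage first clusters the table (K-means, default K=2, in
z-score-standardized feature space), declares the smaller cluster the
minority, and then oversamples the minority *boundary*: a minority row is a
DANGER seed iff at least half but not all of its m nearest neighbors belong
to the majority; rows whose neighbors are all majority are NOISE and rows
with a majority-minority neighborhood are SAFE — neither is used as a seed.

Synthetics are classic SMOTE segments: x_new = x_d + u*(x_nn - x_d) with
u ~ U(0,1), x_d a danger seed (round-robin) and x_nn one of its k nearest
minority rows. SMOTE defines no regression target; by default the target is
interpolated with the same u, keeping synthetics on the local linear
response; optionally the seed's target is copied.

Distances are always computed in the z-scored feature space used for
clustering; interpolation happens in the raw feature space.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans
from sklearn.neighbors import NearestNeighbors

from .data import FeatureTable
from .errors import EmptyClusterError, InvalidSpecError
from .seeding import stage_rng, stage_seed

logger = logging.getLogger(__name__)


@dataclass
class ClusterAssignment:
    """K-means result: per-row labels, centroids in standardized space,
    per-cluster sizes."""

    K: int
    labels: np.ndarray
    centroids: np.ndarray
    sizes: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.sizes = np.asarray(self.sizes, dtype=int)
        if self.labels.min() < 0 or self.labels.max() >= self.K:
            raise InvalidSpecError("labels out of [0, K)")
        if (self.sizes == 0).any():
            raise EmptyClusterError("every cluster must be non-empty")
        if self.sizes.sum() != self.labels.shape[0]:
            raise InvalidSpecError("sizes must sum to n")

    def minority_label(self) -> int:
        """Smallest cluster; ties broken toward the lower index."""
        return int(np.argmin(self.sizes))


@dataclass
class SmoteSpec:
    """Borderline-SMOTE parameters.

    k_neighbors: minority neighbors used for interpolation partners.
    m_neighbors: whole-table neighbors used for the danger classification.
    target_ratio: desired |minority| / |majority| after oversampling.
    interpolate_target: interpolate y with the feature coefficient u
    (default) instead of copying the seed's y.
    """

    k_neighbors: int = 5
    m_neighbors: int = 10
    target_ratio: float = 1.0
    interpolate_target: bool = True
    n_clusters: int = 2

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise InvalidSpecError("k_neighbors must be >= 1")
        if self.m_neighbors < self.k_neighbors:
            raise InvalidSpecError("m_neighbors must be >= k_neighbors")
        if not (0 < self.target_ratio <= 1):
            raise InvalidSpecError("target_ratio must be in (0, 1]")
        if self.n_clusters < 1:
            raise InvalidSpecError("n_clusters must be >= 1")


def standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Z-score with a zero-variance guard (constant features pass through
    unscaled). Returns (Z, mean, scale)."""
    mu = X.mean(axis=0)
    sigma = X.std(axis=0, ddof=0)
    sigma = np.where(sigma == 0, 1.0, sigma)
    return (X - mu) / sigma, mu, sigma


def cluster(table: FeatureTable, K: int = 2, seed: int = 0) -> ClusterAssignment:
    """K-means (k-means++ seeding, Lloyd to tol 1e-6 or 300 iterations, best
    of 10 restarts) on z-scored features; deterministic given *seed*."""
    if table.n < K:
        raise InvalidSpecError(f"n={table.n} < K={K}")
    Z, _, _ = standardize(table.X)
    km = KMeans(
        n_clusters=K,
        init="k-means++",
        n_init=10,
        max_iter=300,
        tol=1e-6,
        random_state=stage_seed(seed, "cluster"),
    ).fit(Z)
    labels = km.labels_.astype(int)
    sizes = np.bincount(labels, minlength=K)
    return ClusterAssignment(K=K, labels=labels, centroids=km.cluster_centers_,
                             sizes=sizes)


def danger_set(
    table: FeatureTable,
    assignment: ClusterAssignment,
    spec: SmoteSpec | None = None,
    minority_label: int | None = None,
) -> np.ndarray:
    """Indices of minority rows on the cluster boundary (DANGER rule).

    Among each minority row's m nearest rows (standardized Euclidean, self
    excluded), let c be the count from outside the minority cluster:
    m/2 <= c < m is DANGER, c == m is NOISE, c < m/2 is SAFE.
    """
    spec = spec or SmoteSpec()
    if minority_label is None:
        minority_label = assignment.minority_label()
    minority_idx = np.flatnonzero(assignment.labels == minority_label)
    if minority_idx.size == 0:
        raise EmptyClusterError(f"cluster {minority_label} is empty")
    Z, _, _ = standardize(table.X)
    m = min(spec.m_neighbors, table.n - 1)
    nn = NearestNeighbors(n_neighbors=m + 1).fit(Z)
    _, idx = nn.kneighbors(Z[minority_idx])
    neigh = idx[:, 1:]  # self is its own nearest neighbor
    is_majority = assignment.labels[neigh] != minority_label
    c = is_majority.sum(axis=1)
    danger = (c >= m / 2) & (c < m)
    return minority_idx[danger]


def smote_augment(
    table: FeatureTable,
    assignment: ClusterAssignment,
    spec: SmoteSpec | None = None,
    seed: int = 0,
) -> FeatureTable:
    """Oversample minority-cluster boundaries; originals pass through
    unchanged and first; synthetics tagged ``smote``.

    With K=2 the smaller cluster is the minority. With K>2 every non-largest
    cluster is treated pairwise as minority against the rest, each brought up
    toward target_ratio times the largest cluster's size.
    """
    spec = spec or SmoteSpec()
    rng = stage_rng(seed, "smote")
    largest = int(np.argmax(assignment.sizes))
    new_X, new_y = [], []

    for label in range(assignment.K):
        if label == largest:
            continue
        n_minority = int(assignment.sizes[label])
        n_majority = int(assignment.sizes[largest])
        n_synth = max(0, math.ceil(spec.target_ratio * n_majority) - n_minority)
        if n_synth == 0:
            continue
        X, y = _smote_for_cluster(table, assignment, spec, label, n_synth, rng)
        new_X.append(X)
        new_y.append(y)

    if not new_X:
        return table.copy()
    synth_X = np.vstack(new_X)
    synth_y = np.concatenate(new_y) if table.has_target else None
    return FeatureTable(
        X=np.vstack([table.X, synth_X]),
        feature_names=table.feature_names,
        y=None if table.y is None else np.concatenate([table.y, synth_y]),
        provenance=np.concatenate(
            [table.provenance, np.full(synth_X.shape[0], "smote", dtype=object)]
        ),
    )


def _smote_for_cluster(
    table: FeatureTable,
    assignment: ClusterAssignment,
    spec: SmoteSpec,
    minority_label: int,
    n_synth: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray | None]:
    minority_idx = np.flatnonzero(assignment.labels == minority_label)
    if minority_idx.size < 2:
        raise EmptyClusterError(
            f"cluster {minority_label} too small for SMOTE ({minority_idx.size} rows)"
        )
    seeds = danger_set(table, assignment, spec, minority_label)
    if seeds.size == 0:
        logger.warning(
            "empty danger set for cluster %d; falling back to classic SMOTE "
            "over all %d minority rows", minority_label, minority_idx.size,
        )
        seeds = minority_idx

    Z, _, _ = standardize(table.X)
    k = min(spec.k_neighbors, minority_idx.size - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(Z[minority_idx])
    _, local = nn.kneighbors(Z[seeds])
    # map local minority indices back to table rows; drop the seed itself
    partner_rows = minority_idx[local]
    partners = np.empty((seeds.size, k), dtype=int)
    for i, s in enumerate(seeds):
        row = partner_rows[i]
        row = row[row != s][:k]
        partners[i] = row

    d_pos = np.arange(n_synth) % seeds.size  # round-robin over danger seeds
    choice = rng.integers(0, k, size=n_synth)
    u = rng.uniform(0.0, 1.0, size=n_synth)
    xd = table.X[seeds[d_pos]]
    xn = table.X[partners[d_pos, choice]]
    synth_X = xd + u[:, None] * (xn - xd)

    synth_y = None
    if table.has_target:
        yd = table.y[seeds[d_pos]]
        yn = table.y[partners[d_pos, choice]]
        synth_y = yd + u * (yn - yd) if spec.interpolate_target else yd
    return synth_X, synth_y
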