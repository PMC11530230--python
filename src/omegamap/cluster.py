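"""Embedding and density-based clustering of featurized conformations.

Feature rows are embedded with UMAP into a 10-dimensional space
(conventional neighbor count 30 and min_dist 0.1, both configurable) and
partitioned with HDBSCAN, whose single effective knob is
the minimum cluster occupancy as a fraction of the ensemble size.  Points
the density clustering leaves unassigned are reported as *noise* (label
-1) and excluded from every cluster; clusters are renumbered 1..K by
decreasing occupancy for report stability (the numbering itself carries no
meaning).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import HDBSCAN
from sklearn.metrics import adjusted_rand_score

from .featurize import FeatureMatrix

NOISE = -1


@dataclass
class Embedding:
    """Low-dimensional UMAP embedding of the feature rows."""

    points: np.ndarray
    seed: int
    settings: dict = field(default_factory=dict)

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    @property
    def dim(self) -> int:
        return self.points.shape[1]


@dataclass
class ClusterAssignment:
    """Per-conformation labels: 1..K for clusters, -1 for noise."""

    labels: np.ndarray
    min_cluster_fraction: float = 0.0

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def K(self) -> int:
        return int(self.labels.max(initial=0))

    @property
    def noise_mask(self) -> np.ndarray:
        return self.labels == NOISE

    @property
    def noise_fraction(self) -> float:
        return float(self.noise_mask.mean())

    def members(self, k: int) -> np.ndarray:
        """Conformation indices (0-based) of cluster ``k`` in 1..K."""
        if not 1 <= k <= self.K:
            raise IndexError(f"cluster id {k} outside 1..{self.K}")
        return np.flatnonzero(self.labels == k)

    def sizes(self) -> np.ndarray:
        """Occupancy of clusters 1..K (non-increasing by construction)."""
        return np.array([(self.labels == k).sum() for k in range(1, self.K + 1)])


def _renumber_by_occupancy(raw_labels: np.ndarray) -> np.ndarray:
    """Map arbitrary non-noise labels to 1..K by decreasing cluster size
    (ties broken by the original label for determinism)."""
    out = np.full_like(raw_labels, NOISE)
    uniq, counts = np.unique(raw_labels[raw_labels != NOISE], return_counts=True)
    order = sorted(zip(uniq, counts), key=lambda uc: (-uc[1], uc[0]))
    for new, (old, _cnt) in enumerate(order, start=1):
        out[raw_labels == old] = new
    return out


def embed(features: FeatureMatrix | np.ndarray, dim: int = 10, seed: int = 0,
          n_neighbors: int = 30, min_dist: float = 0.1) -> Embedding:
    """UMAP embedding of feature rows (Euclidean metric).

    Deterministic for a fixed seed and library version.  ``dim=2`` gives
    the visualization projection; ``dim=10`` (default) feeds clustering.
    """
    X = features.values if isinstance(features, FeatureMatrix) else np.asarray(features)
    if X.shape[0] < n_neighbors:
        raise ValueError(
            f"n = {X.shape[0]} < n_neighbors = {n_neighbors}; "
            "lower n_neighbors for small ensembles"
        )
    import umap

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reducer = umap.UMAP(n_components=dim, n_neighbors=n_neighbors,
                            min_dist=min_dist, metric="euclidean",
                            random_state=seed)
        points = reducer.fit_transform(X)
    return Embedding(points=np.asarray(points, float), seed=seed,
                     settings={"dim": dim, "n_neighbors": n_neighbors,
                               "min_dist": min_dist})


def partition(emb: Embedding | np.ndarray,
              min_cluster_fraction: float = 0.01,
              min_samples: int | None = None) -> ClusterAssignment:
    """HDBSCAN partition of an embedding.

    ``min_cluster_size = max(2, round(min_cluster_fraction * n))``; the
    cluster count K is selected by the algorithm, unassigned points are
    noise.  Defaults ``min_samples`` to ``min_cluster_size`` so occupancy
    remains the single knob.
    """
    if not 0.0 < min_cluster_fraction < 1.0:
        raise ValueError("min_cluster_fraction must be in (0, 1)")
    X = emb.points if isinstance(emb, Embedding) else np.asarray(emb)
    n = X.shape[0]
    min_cluster_size = max(2, int(round(min_cluster_fraction * n)))
    if np.allclose(X, X[0]):
        warnings.warn("degenerate embedding: all points identical; one cluster",
                      stacklevel=2)
        return ClusterAssignment(np.ones(n, dtype=int), min_cluster_fraction)
    clusterer = HDBSCAN(
        min_cluster_size=min_cluster_size,
        min_samples=min_samples if min_samples is not None else min_cluster_size,
        copy=True,
    )
    raw = clusterer.fit_predict(X)
    return ClusterAssignment(_renumber_by_occupancy(raw), min_cluster_fraction)


def adjusted_rand_index(a: ClusterAssignment | np.ndarray,
                        b: ClusterAssignment | np.ndarray,
                        exclude_noise: bool = False) -> float:
    """Chance-corrected agreement between two partitions of the same items.

    Noise is treated as its own class by default; with ``exclude_noise``
    points flagged noise in either partition are dropped first.
    """
    la = a.labels if isinstance(a, ClusterAssignment) else np.asarray(a)
    lb = b.labels if isinstance(b, ClusterAssignment) else np.asarray(b)
    if len(la) != len(lb):
        raise ValueError(f"partition lengths differ: {len(la)} != {len(lb)}")
    if exclude_noise:
        keep = (la != NOISE) & (lb != NOISE)
        la, lb = la[keep], lb[keep]
    return float(adjusted_rand_score(la, lb))


class UmapHdbscanClusterer:
    """Scikit-learn style clusterer chaining UMAP and HDBSCAN.

    ``fit(X)`` on an (n, p) feature array sets ``embedding_`` (the
    intermediate UMAP points), ``labels_`` (1..K, noise -1) and
    ``assignment_``.
    """

    def __init__(self, dim: int = 10, n_neighbors: int = 30,
                 min_dist: float = 0.1, min_cluster_fraction: float = 0.01,
                 random_state: int = 0):
        self.dim = dim
        self.n_neighbors = n_neighbors
        self.min_dist = min_dist
        self.min_cluster_fraction = min_cluster_fraction
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in
                ("dim", "n_neighbors", "min_dist", "min_cluster_fraction",
                 "random_state")}

    def set_params(self, **params) -> "UmapHdbscanClusterer":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y=None) -> "UmapHdbscanClusterer":
        emb = embed(X, dim=self.dim, seed=self.random_state,
                    n_neighbors=self.n_neighbors, min_dist=self.min_dist)
        assignment = partition(emb, self.min_cluster_fraction)
        self.embedding_ = emb
        self.assignment_ = assignment
        self.labels_ = assignment.labels
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X, y).labels_
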