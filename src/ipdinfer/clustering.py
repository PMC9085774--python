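"""Two-level K-means clustering of IPD players.

Level one (*contextual*) groups players by how often they experienced each
of the four contexts; level two (*behavioral*) splits each contextual
cluster by the counts of cooperative responses per context.  The number of
clusters is chosen by the elbow (kneedle) rule on the inertia curve, and
cluster quality is reported as the mean silhouette coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score as _sk_silhouette

CONTEXT_FEATURES = ["n_cc", "n_cd", "n_dc", "n_dd"]
BEHAVIOR_FEATURES = ["c_cc", "c_cd", "c_dc", "c_dd"]

# identical feature rows up to this total squared deviation count as degenerate
_DEGENERATE_TOL = 1e-9


@dataclass
class ClusterModel:
    """A fitted K-means partition at one level of the hierarchy."""

    level: str  # "contextual" or "behavioral"
    k: int
    labels: np.ndarray
    centers: np.ndarray
    inertia: float
    silhouette: float | None
    players: list[str] = field(default_factory=list)
    inertia_curve: dict[int, float] = field(default_factory=dict)

    def members(self, cluster: int) -> list[str]:
        return [p for p, lab in zip(self.players, self.labels) if lab == cluster]


def kmeans_fit(
    X: np.ndarray, k: int, seed: int = 0, n_restarts: int = 10, level: str = "contextual"
) -> ClusterModel:
    """Best-of-restarts Lloyd K-means, deterministic given the seed."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("X must be a 2-D feature matrix")
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds number of points {X.shape[0]}")
    if k < 1:
        raise ValueError("k must be >= 1")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(X)
    sil = None
    if 2 <= k < X.shape[0] and len(np.unique(labels)) >= 2:
        sil = float(_sk_silhouette(X, labels))
    return ClusterModel(
        level=level,
        k=k,
        labels=labels,
        centers=km.cluster_centers_,
        inertia=float(km.inertia_),
        silhouette=sil,
    )


def silhouette_score(X: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette coefficient (b - a) / max(a, b), Euclidean distances.

    Singleton clusters contribute 0, following the usual convention.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette undefined for a single cluster")
    return float(_sk_silhouette(np.asarray(X, dtype=float), labels))


def elbow_select(inertias: list[float] | np.ndarray) -> int:
    """Pick k at the knee of the inertia curve for k = 1..K_max.

    After a monotone repair (running minimum) and min-max normalization of
    both axes, the knee is the interior k with the largest vertical distance
    below the chord joining the curve's endpoints; ties break toward the
    smaller k.  A flat curve (all inertias equal) returns k = 1.
    """
    y = np.asarray(inertias, dtype=float)
    k_max = len(y)
    if k_max < 3:
        raise ValueError("elbow selection needs inertias for at least k=1..3")
    y = np.minimum.accumulate(y)  # enforce non-increasing
    span = y[0] - y[-1]
    if span <= _DEGENERATE_TOL:
        return 1
    y_norm = (y - y[-1]) / span
    x_norm = np.linspace(0.0, 1.0, k_max)
    chord = 1.0 - x_norm  # line from (0, 1) to (1, 0)
    distances = chord - y_norm
    interior = np.arange(1, k_max - 1)  # indices of k = 2..K_max-1
    best = interior[np.argmax(distances[interior])]  # argmax takes first on ties
    return int(best) + 1


def _select_and_fit(
    X: np.ndarray,
    players: list[str],
    k_max: int,
    seed: int,
    n_restarts: int,
    level: str,
) -> ClusterModel:
    """Run K-means over k = 1..k_max, pick k by elbow, refit, attach curve."""
    n = X.shape[0]
    total_ss = float(((X - X.mean(axis=0)) ** 2).sum())
    if total_ss <= _DEGENERATE_TOL:
        # all players identical: a single trivial cluster, no silhouette
        model = ClusterModel(
            level=level,
            k=1,
            labels=np.zeros(n, dtype=int),
            centers=X.mean(axis=0, keepdims=True),
            inertia=0.0,
            silhouette=None,
            players=players,
        )
        model.inertia_curve = {1: 0.0}
        return model
    n_distinct = len(np.unique(X, axis=0))
    k_cap = min(k_max, n - 1, n_distinct)
    curve = {
        k: kmeans_fit(X, k, seed=seed, n_restarts=n_restarts, level=level).inertia
        for k in range(1, k_cap + 1)
    }
    if k_cap < 3:
        k_star = k_cap
    else:
        k_star = elbow_select([curve[k] for k in range(1, k_cap + 1)])
    model = kmeans_fit(X, k_star, seed=seed, n_restarts=n_restarts, level=level)
    model.players = players
    model.inertia_curve = curve
    return model


def contextual_cluster(
    profile_df: pd.DataFrame,
    k_max: int = 8,
    seed: int = 0,
    n_restarts: int = 10,
    normalize: bool = False,
) -> ClusterModel:
    """Cluster players on their four context counts (CC, CD, DC, DD).

    ``normalize`` divides counts by each player's sequence length, for
    imports with variable-length games; with a fixed round count the raw
    counts and the frequencies are proportional.
    """
    X = profile_df[CONTEXT_FEATURES].to_numpy(dtype=float)
    if normalize:
        X = X / X.sum(axis=1, keepdims=True)
    return _select_and_fit(
        X, list(profile_df.index), k_max, seed, n_restarts, "contextual"
    )


def behavioral_subcluster(
    profile_df: pd.DataFrame,
    k_max: int = 6,
    seed: int = 0,
    n_restarts: int = 10,
) -> ClusterModel:
    """Sub-cluster one contextual cluster on cooperative-response counts.

    Clusters with fewer than 4 members pass through as a single sub-cluster;
    there is too little data to split them meaningfully.
    """
    X = profile_df[BEHAVIOR_FEATURES].to_numpy(dtype=float)
    players = list(profile_df.index)
    if len(players) < 4:
        return ClusterModel(
            level="behavioral",
            k=1,
            labels=np.zeros(len(players), dtype=int),
            centers=X.mean(axis=0, keepdims=True) if len(players) else np.zeros((1, 4)),
            inertia=0.0,
            silhouette=None,
            players=players,
        )
    return _select_and_fit(X, players, k_max, seed, n_restarts, "behavioral")
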