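"""Functional clustering of dyads by synchronization level.

K-means (k = 3, many restarts) on the one-dimensional feature "per-dyad
mean near-in-phase percentage", run independently per pitch axis. Clusters
are ranked by centroid and labelled higher / intermediate / lower, giving a
coarse map of which pairs of players move together most.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

__all__ = ["ClusterAssignment", "cluster_dyads", "GROUP_LABELS"]

GROUP_LABELS = ("higher", "intermediate", "lower")


@dataclass
class ClusterAssignment:
    """One dyad's synchronization group on one axis."""

    axis: str
    dyad: tuple
    group: str
    group_centroid: float  # %
    group_sd: float        # %


def cluster_dyads(
    features: dict[tuple, float],
    k: int = 3,
    seed: int = 0,
    n_restarts: int = 50,
    axis: str = "",
) -> list[ClusterAssignment]:
    """Partition dyads into k synchronization-level groups.

    Parameters
    ----------
    features:
        Mapping dyad -> synchronization percentage (one number per dyad,
        typically the mean over matches).
    k:
        Number of groups; 3 yields the higher/intermediate/lower labels.
    seed, n_restarts:
        K-means is restarted ``n_restarts`` times from k-means++ seeds;
        with 1-D data of this size the best restart attains the global
        within-cluster-SS optimum in practice.

    Returns one assignment per dyad; groups are ordered by descending
    centroid and all k groups are guaranteed non-empty.
    """
    dyads = sorted(features)
    values = np.array([features[d] for d in dyads], dtype=float)
    if np.any(~np.isfinite(values)):
        raise ValueError("non-finite synchronization features")
    if len(np.unique(values)) < k:
        raise ValueError(
            f"need at least {k} distinct feature values, got {len(np.unique(values))}"
        )
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(values.reshape(-1, 1))
    centroids = km.cluster_centers_.ravel()
    if len(np.unique(labels)) < k:
        raise ValueError("k-means produced an empty cluster")

    order = np.argsort(-centroids)  # descending centroid -> rank
    rank_of = {int(c): r for r, c in enumerate(order)}
    names = GROUP_LABELS if k == 3 else tuple(f"group_{i + 1}" for i in range(k))

    out = []
    for d, lab, v in zip(dyads, labels, values):
        r = rank_of[int(lab)]
        members = values[labels == lab]
        out.append(ClusterAssignment(
            axis=axis,
            dyad=d,
            group=names[r],
            group_centroid=float(centroids[lab]),
            group_sd=float(members.std(ddof=1)) if len(members) > 1 else 0.0,
        ))
    return out
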