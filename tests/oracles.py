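"""Independent reference implementations used only as test oracles.

These deliberately use different derivations from the production code:
the UTM forward here follows the classic Snyder/USGS truncated series
(Map Projections: A Working Manual, eq. 8-9ff), not the Krueger series in
``teamsync.geo``; the clustering oracle is an exact O(k n^2) dynamic
program over sorted 1-D data, not Lloyd iterations.
"""

from __future__ import annotations

import numpy as np

# WGS84
_A = 6378137.0
_F = 1 / 298.257223563
_E2 = _F * (2 - _F)
_EP2 = _E2 / (1 - _E2)
_K0 = 0.9996


def snyder_utm_forward(lat_deg, lon_deg, zone):
    """USGS/Snyder series transverse Mercator forward projection."""
    phi = np.radians(np.asarray(lat_deg, dtype=float))
    lam = np.radians(np.asarray(lon_deg, dtype=float) - (zone * 6 - 183))
    e2, ep2 = _E2, _EP2
    N = _A / np.sqrt(1 - e2 * np.sin(phi) ** 2)
    T = np.tan(phi) ** 2
    C = ep2 * np.cos(phi) ** 2
    Aa = lam * np.cos(phi)
    M = _A * (
        (1 - e2 / 4 - 3 * e2**2 / 64 - 5 * e2**3 / 256) * phi
        - (3 * e2 / 8 + 3 * e2**2 / 32 + 45 * e2**3 / 1024) * np.sin(2 * phi)
        + (15 * e2**2 / 256 + 45 * e2**3 / 1024) * np.sin(4 * phi)
        - (35 * e2**3 / 3072) * np.sin(6 * phi)
    )
    x = _K0 * N * (
        Aa
        + (1 - T + C) * Aa**3 / 6
        + (5 - 18 * T + T**2 + 72 * C - 58 * ep2) * Aa**5 / 120
    )
    y = _K0 * (
        M
        + N * np.tan(phi) * (
            Aa**2 / 2
            + (5 - T + 9 * C + 4 * C**2) * Aa**4 / 24
            + (61 - 58 * T + T**2 + 600 * C - 330 * ep2) * Aa**6 / 720
        )
    )
    return x + 500_000.0, y


def meridian_radius(lat_deg):
    """Meridian radius of curvature M(phi) on WGS84, metres."""
    phi = np.radians(lat_deg)
    return _A * (1 - _E2) / (1 - _E2 * np.sin(phi) ** 2) ** 1.5


def dp_kmeans_1d(values, k):
    """Exact minimum within-cluster sum of squares for 1-D k-means.

    Returns (optimal_sse, labels aligned with the input order). Clusters
    of sorted data are contiguous, so an O(k n^2) dynamic program over
    split points is exact.
    """
    values = np.asarray(values, dtype=float)
    order = np.argsort(values, kind="stable")
    x = values[order]
    n = len(x)
    ps = np.concatenate([[0.0], np.cumsum(x)])
    ps2 = np.concatenate([[0.0], np.cumsum(x**2)])

    def sse(i, j):  # cost of cluster x[i:j]
        s = ps[j] - ps[i]
        return (ps2[j] - ps2[i]) - s * s / (j - i)

    INF = float("inf")
    cost = np.full((k + 1, n + 1), INF)
    back = np.zeros((k + 1, n + 1), dtype=int)
    cost[0, 0] = 0.0
    for c in range(1, k + 1):
        for j in range(c, n + 1):
            for i in range(c - 1, j):
                v = cost[c - 1, i] + sse(i, j)
                if v < cost[c, j]:
                    cost[c, j] = v
                    back[c, j] = i
    labels_sorted = np.empty(n, dtype=int)
    j = n
    for c in range(k, 0, -1):
        i = back[c, j]
        labels_sorted[i:j] = c - 1
        j = i
    labels = np.empty(n, dtype=int)
    labels[order] = labels_sorted
    return float(cost[k, n]), labels
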