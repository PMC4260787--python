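"""Chebyshev-ball neighbour statistics for the (C)MI estimators.

Points are sorted along their first coordinate once per sample cloud; both
the k-th-neighbour distance and the per-point strict ball counts are then
computed by scanning the sorted window that the first coordinate admits,
pruning on the current k-th-best distance. This beats generic k-d trees at
the low dimensions (1–6) these estimators live in. A pure-numpy/scipy
fallback is used when numba is unavailable.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard speed dependency
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f
        return wrap if not (args and callable(args[0])) else args[0]


class SortedCloud:
    """A point cloud sorted by its first coordinate, reusable across
    multiple radius-count queries."""

    __slots__ = ("pts", "order")

    def __init__(self, pts: np.ndarray):
        pts = np.ascontiguousarray(pts, dtype=np.float64)
        self.order = np.argsort(pts[:, 0], kind="stable")
        self.pts = np.ascontiguousarray(pts[self.order])


@njit(cache=True)
def _kth_scan(pts: np.ndarray, k: int) -> np.ndarray:
    """k-th nearest-neighbour Chebyshev distance per point (self excluded)
    of points sorted by column 0."""
    n, d = pts.shape
    eps = np.empty(n)
    best = np.empty(k)
    for i in range(n):
        for m in range(k):
            best[m] = np.inf
        kth = np.inf
        left = i - 1
        right = i + 1
        while True:
            dl = pts[i, 0] - pts[left, 0] if left >= 0 else np.inf
            dr = pts[right, 0] - pts[i, 0] if right < n else np.inf
            if dl >= kth and dr >= kth:
                break
            if dl <= dr:
                j = left
                left -= 1
                dist = dl
            else:
                j = right
                right += 1
                dist = dr
            for c in range(1, d):
                diff = abs(pts[i, c] - pts[j, c])
                if diff > dist:
                    dist = diff
            if dist < kth:
                m = k - 1
                while m > 0 and best[m - 1] > dist:
                    best[m] = best[m - 1]
                    m -= 1
                best[m] = dist
                kth = best[k - 1]
        eps[i] = kth
    return eps


@njit(cache=True)
def _count_scan(pts: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Number of points strictly within Chebyshev radius r[i] of point i
    (self excluded), points sorted by column 0, r aligned with pts."""
    n, d = pts.shape
    out = np.zeros(n, dtype=np.int64)
    for i in range(n):
        ri = r[i]
        c = 0
        j = i - 1
        while j >= 0 and pts[i, 0] - pts[j, 0] < ri:
            ok = True
            for m in range(1, d):
                if abs(pts[i, m] - pts[j, m]) >= ri:
                    ok = False
                    break
            if ok:
                c += 1
            j -= 1
        j = i + 1
        while j < n and pts[j, 0] - pts[i, 0] < ri:
            ok = True
            for m in range(1, d):
                if abs(pts[i, m] - pts[j, m]) >= ri:
                    ok = False
                    break
            if ok:
                c += 1
            j += 1
        out[i] = c
    return out


def kth_distance(points: np.ndarray, k: int) -> np.ndarray:
    """Distance to the k-th nearest neighbour (Chebyshev, self excluded)."""
    if HAVE_NUMBA:
        cloud = SortedCloud(points)
        eps = np.empty(len(points))
        eps[cloud.order] = _kth_scan(cloud.pts, k)
    else:  # pragma: no cover
        from scipy.spatial import cKDTree
        eps, _ = cKDTree(points).query(points, k=k + 1, p=np.inf)
        eps = eps[:, -1]
    # duplicate points collapse eps to 0; keep the ball non-degenerate
    return np.maximum(eps, 1e-300)


def count_within(points: np.ndarray, eps: np.ndarray,
                 cloud: SortedCloud | None = None) -> np.ndarray:
    """Per-point count of neighbours strictly inside radius eps
    (self excluded)."""
    points = np.asarray(points, dtype=np.float64)
    if HAVE_NUMBA:
        if cloud is None:
            cloud = SortedCloud(points)
        out = np.empty(len(points), dtype=np.int64)
        out[cloud.order] = _count_scan(cloud.pts, eps[cloud.order])
        return out
    from scipy.spatial import cKDTree  # pragma: no cover
    return np.asarray(cKDTree(points).query_ball_point(  # pragma: no cover
        points, np.nextafter(eps, 0.0), p=np.inf, return_length=True)) - 1
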