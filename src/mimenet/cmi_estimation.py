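"""k-nearest-neighbour estimators for mutual information and conditional
mutual information.

Both estimators work on continuous sample clouds using Chebyshev-ball
neighbour counts: plain MI follows Kraskov, Stögbauer & Grassberger
(algorithm 1), and conditional MI follows the Frenzel–Pompe extension.
Estimates are in nats. Raw estimates can be slightly negative; callers that
need the nonnegativity of true (C)MI should pass ``clamp=True`` or clamp
themselves.
"""

from __future__ import annotations

import numpy as np
from scipy.special import digamma

from ._neighbors import SortedCloud, count_within, kth_distance

__all__ = [
    "as_cloud",
    "jitter",
    "estimate_mi",
    "estimate_cmi",
    "MIN_POINTS",
]

#: floor below which neighbour statistics are meaningless
MIN_POINTS = 50

#: amplitude of the tie-breaking jitter added to quantised signals
JITTER_AMPLITUDE = 1e-10


def as_cloud(a: np.ndarray, name: str = "cloud") -> np.ndarray:
    """Coerce ``a`` to a 2-D float array of shape (n_points, dim).

    1-D input is treated as a single coordinate. Raises ``ValueError`` on
    NaN/Inf entries.
    """
    a = np.asarray(a, dtype=np.float64)
    if a.ndim == 1:
        a = a[:, None]
    if a.ndim != 2:
        raise ValueError(f"{name} must be 1- or 2-dimensional, got ndim={a.ndim}")
    if a.size and not np.all(np.isfinite(a)):
        raise ValueError(f"{name} contains NaN or Inf entries")
    return a


def jitter(a: np.ndarray, rng: np.random.Generator,
           amplitude: float = JITTER_AMPLITUDE) -> np.ndarray:
    """Return ``a`` plus seeded uniform noise of the given amplitude.

    Breaks exact ties in neighbour distances, which otherwise bias the
    Chebyshev-ball counts on quantised (e.g. digitised) signals.
    """
    a = np.asarray(a, dtype=np.float64)
    return a + rng.uniform(-amplitude, amplitude, size=a.shape)


def _validate(k: int, n: int) -> None:
    if n < MIN_POINTS:
        raise ValueError(f"need at least {MIN_POINTS} points, got {n}")
    if k >= n:
        raise ValueError(f"k={k} must be smaller than n_points={n}")
    if k < 1:
        raise ValueError("k must be >= 1")


def estimate_mi(x: np.ndarray, y: np.ndarray, k: int = 4, *,
                clamp: bool = False,
                _cloud_x: SortedCloud | None = None) -> float:
    """KSG estimate of the mutual information I(X;Y) in nats.

    Parameters
    ----------
    x, y : arrays of shape (n,) or (n, d)
        Paired samples.
    k : int
        Neighbour count in the joint space.
    clamp : bool
        If true, negative raw estimates are clamped to 0.
    """
    x = as_cloud(x, "x")
    y = as_cloud(y, "y")
    if x.shape[0] != y.shape[0]:
        raise ValueError(
            f"x and y must have the same n_points ({x.shape[0]} != {y.shape[0]})"
        )
    n = x.shape[0]
    _validate(k, n)

    eps = kth_distance(np.hstack((x, y)), k)
    n_x = count_within(x, eps, _cloud_x)
    n_y = count_within(y, eps)
    mi = (digamma(k) + digamma(n)
          - float(np.mean(digamma(n_x + 1) + digamma(n_y + 1))))
    return max(mi, 0.0) if clamp else mi


def estimate_cmi(x: np.ndarray, y: np.ndarray, z: np.ndarray | None,
                 k: int = 4, *, clamp: bool = False,
                 _cloud_xz: SortedCloud | None = None,
                 _cloud_z: SortedCloud | None = None) -> float:
    """Frenzel–Pompe estimate of the conditional mutual information
    I(X;Y|Z) in nats.

    With an empty conditioning set (``z`` is None or has zero columns) this
    reduces exactly to :func:`estimate_mi`.

    The private ``_cloud_*`` arguments let callers that sweep many ``y``
    candidates against a fixed (x, z) reuse the sorted marginal clouds; the
    returned value is bit-identical to the cloud-free call.
    """
    x = as_cloud(x, "x")
    y = as_cloud(y, "y")
    if z is None or (hasattr(z, "shape") and as_cloud(z, "z").shape[1] == 0):
        return estimate_mi(x, y, k, clamp=clamp, _cloud_x=_cloud_xz)
    z = as_cloud(z, "z")
    n = x.shape[0]
    if not (y.shape[0] == n and z.shape[0] == n):
        raise ValueError("x, y, z must have the same n_points")
    _validate(k, n)

    eps = kth_distance(np.hstack((x, y, z)), k)
    n_xz = count_within(np.hstack((x, z)), eps, _cloud_xz)
    n_yz = count_within(np.hstack((y, z)), eps)
    n_z = count_within(z, eps, _cloud_z)
    cmi = digamma(k) - float(
        np.mean(digamma(n_xz + 1) + digamma(n_yz + 1) - digamma(n_z + 1))
    )
    return max(cmi, 0.0) if clamp else cmi
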