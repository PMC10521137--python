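"""k-nearest-neighbour tricube loess on a uniform grid.

Local polynomial regression in the classic loess form: at every grid point
the ``neighbours`` nearest points are fitted with a weighted polynomial of
the given ``order`` using tricube weights, and the fit is evaluated at that
point. The defaults (15 neighbours, order 2) follow the fork-probe
smoothing convention used throughout this package.

On a uniform grid the interior stencil is translation invariant, so the
interior reduces to a single convolution; edge points are solved
individually with the same weighted least squares. Constants are reproduced
exactly for any order, and quadratics are reproduced exactly at order >= 2,
because the local model contains them.
"""

from __future__ import annotations

import numpy as np


def _point_weights(offsets: np.ndarray) -> np.ndarray:
    """Tricube weights over integer offsets; max |offset| gets weight 0."""
    d = np.abs(offsets).astype(float)
    dmax = d.max()
    if dmax == 0:
        return np.ones_like(d)
    u = np.clip(d / dmax, 0.0, 1.0)
    return (1.0 - u**3) ** 3


def _fit_row(offsets: np.ndarray, order: int) -> np.ndarray:
    """Row of the local-regression hat matrix evaluated at offset 0.

    Returns coefficients ``c`` with smoothed value = c @ y[window].
    """
    w = _point_weights(offsets)
    # Vandermonde in the local coordinate; evaluation point is offset 0, so
    # only the constant term of the weighted LSQ solution is needed.
    X = np.vander(offsets.astype(float), N=order + 1, increasing=True)
    WX = X * w[:, None]
    # c_row = e0^T (X^T W X)^{-1} X^T W
    xtwx = X.T @ WX
    xtw = (X * w[:, None]).T
    sol = np.linalg.solve(xtwx, xtw)
    return sol[0]


def loess_smooth(y: np.ndarray, neighbours: int = 15, order: int = 2) -> np.ndarray:
    """Smooth ``y`` (values on a uniform grid) by k-NN tricube loess.

    Parameters
    ----------
    y
        Signal vector.
    neighbours
        Number of nearest grid points in each local fit (the loess span,
        expressed as a count). Must satisfy ``neighbours >= order + 1`` and
        ``len(y) > neighbours`` is not required — equality is allowed — but
        ``len(y) >= neighbours`` is.
    order
        Degree of the local polynomial.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if neighbours < order + 1:
        raise ValueError("neighbours must be at least order + 1")
    if n < neighbours:
        raise ValueError(f"signal has {n} bins, fewer than {neighbours} neighbours")
    if not np.all(np.isfinite(y)):
        raise ValueError("signal contains non-finite values")

    k = neighbours
    out = np.empty(n)
    half = (k - 1) // 2
    # Interior: the k-nearest window of an interior point i is the contiguous
    # block centred on it, identical up to translation -> one stencil.
    lo_interior = half
    hi_interior = n - (k - 1 - half)  # exclusive
    if hi_interior > lo_interior:
        offsets = np.arange(k) - half
        row = _fit_row(offsets, order)
        conv = np.convolve(y, row[::-1], mode="valid")
        out[lo_interior:hi_interior] = conv
    # Edges: the k-nearest set is the clipped contiguous block.
    for i in list(range(0, min(lo_interior, n))) + list(range(max(hi_interior, 0), n)):
        start = min(max(i - half, 0), n - k)
        offsets = np.arange(start, start + k) - i
        row = _fit_row(offsets, order)
        out[i] = row @ y[start : start + k]
    return out
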