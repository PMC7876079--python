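"""Functional kernels for longitudinal abundance data.

A taxon followed over time in one individual is a function f(t).  The
functional linear kernel is the L2 inner product of two such functions
and the functional RBF kernel is exp(-gamma * squared L2 distance).
Both exist in two flavours:

* discrete — the time series itself on a common, evenly spaced grid
  (no interpolation; the sound choice when only a few time points exist);
* continuous — piecewise-linear reconstruction of each series and exact
  integration, tolerating irregular and missing time points.

For multivariate series (many taxa at once) the per-taxon linear kernels
are summed and the per-taxon RBF kernels multiplied, which is equivalent
to a linear / RBF kernel on the individuals x (taxa * time) flattened
matrix.  Complexity is O(N^2 T D).
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .kernels import KernelMatrix
from .tables import TimeSeriesTable

__all__ = [
    "flin_discrete",
    "frbf_discrete",
    "flin_continuous",
    "frbf_continuous",
    "flin_multivariate",
    "frbf_multivariate",
]


def _pair(f, g) -> tuple[np.ndarray, np.ndarray]:
    f = np.asarray(f, dtype=float)
    g = np.asarray(g, dtype=float)
    if f.ndim != 1 or g.ndim != 1 or f.size != g.size:
        raise ValueError(f"series must be 1-D of equal length, got {f.shape} vs {g.shape}")
    if f.size == 0:
        raise ValueError("series must contain at least one time point")
    return f, g


def flin_discrete(f, g, dt: float) -> float:
    """Discrete functional linear kernel: dt * sum_i f(t_i) g(t_i)."""
    f, g = _pair(f, g)
    if not np.isfinite(dt) or dt <= 0:
        raise ValueError(f"dt must be a positive real, got {dt}")
    return float(dt * np.dot(f, g))


def frbf_discrete(f, g, gamma: float) -> float:
    """Discrete functional RBF kernel: exp(-gamma * sum_i (f - g)^2)."""
    f, g = _pair(f, g)
    if not np.isfinite(gamma) or gamma <= 0:
        raise ValueError(f"gamma must be a positive real, got {gamma}")
    return float(np.exp(-gamma * np.sum((f - g) ** 2)))


def _interp_grid(tf, f, tg, g, interval):
    tf = np.asarray(tf, dtype=float)
    tg = np.asarray(tg, dtype=float)
    f = np.asarray(f, dtype=float)
    g = np.asarray(g, dtype=float)
    a, b = float(interval[0]), float(interval[1])
    if b <= a:
        raise ValueError(f"interval must satisfy t_a < t_b, got ({a}, {b})")
    for name, t in (("f", tf), ("g", tg)):
        if t.size < 2:
            raise ValueError(f"series {name} needs at least two sampled points")
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"series {name} times must be strictly increasing")
        if a < t[0] - 1e-12 or b > t[-1] + 1e-12:
            raise ValueError(
                f"interval [{a:g}, {b:g}] lies outside the sampled support "
                f"[{t[0]:g}, {t[-1]:g}] of series {name}; refusing to extrapolate"
            )
    knots = np.unique(np.concatenate([tf, tg, [a, b]]))
    knots = knots[(knots >= a) & (knots <= b)]
    fk = np.interp(knots, tf, f)
    gk = np.interp(knots, tg, g)
    return knots, fk, gk, tf, f, tg, g


def _simpson_segments(knots, values_at, tf, f, tg, g, integrand):
    """Exact integral of a piecewise-quadratic integrand via per-segment Simpson.

    Between consecutive knots both reconstructions are linear, so the
    product (or squared difference) is quadratic and Simpson's rule on the
    segment is exact.
    """
    mids = (knots[:-1] + knots[1:]) / 2.0
    fm = np.interp(mids, tf, f)
    gm = np.interp(mids, tg, g)
    left = integrand(values_at[0][:-1], values_at[1][:-1])
    right = integrand(values_at[0][1:], values_at[1][1:])
    middle = integrand(fm, gm)
    h = np.diff(knots)
    return float(np.sum(h / 6.0 * (left + 4.0 * middle + right)))


def flin_continuous(tf, f, tg, g, interval) -> float:
    """Continuous functional linear kernel: integral of f(t) g(t) over [t_a, t_b].

    Both series are reconstructed by piecewise-linear interpolation on the
    union of their sampling grids; the resulting piecewise-quadratic
    product is integrated exactly.
    """
    knots, fk, gk, tf, f, tg, g = _interp_grid(tf, f, tg, g, interval)
    return _simpson_segments(knots, (fk, gk), tf, f, tg, g, lambda u, v: u * v)


def frbf_continuous(tf, f, tg, g, interval, gamma: float) -> float:
    """Continuous functional RBF kernel: exp(-gamma * integral of |f - g|^2)."""
    if not np.isfinite(gamma) or gamma <= 0:
        raise ValueError(f"gamma must be a positive real, got {gamma}")
    knots, fk, gk, tf, f, tg, g = _interp_grid(tf, f, tg, g, interval)
    d2 = _simpson_segments(knots, (fk, gk), tf, f, tg, g, lambda u, v: (u - v) ** 2)
    return float(np.exp(-gamma * d2))


def _flat(ts: TimeSeriesTable) -> np.ndarray:
    if ts.has_missing():
        raise ValueError(
            "time series has missing points; use the continuous functional kernels"
        )
    return ts.flattened()


def _meta(ts: TimeSeriesTable, name: str, **extra) -> dict:
    return {
        "name": name,
        "preprocessing": list(ts.provenance),
        "times": [float(t) for t in ts.times],
        "n_taxa": ts.n_taxa,
        **extra,
    }


def flin_multivariate(ts: TimeSeriesTable, dt: float | None = None) -> KernelMatrix:
    """Multivariate discrete functional linear kernel matrix.

    Sums the per-taxon discrete linear kernels over all taxa, i.e.
    ``dt *`` linear kernel on the flattened individuals x (taxa * time)
    matrix.  ``dt`` defaults to the (regular) grid spacing.
    """
    flat = _flat(ts)
    if dt is None:
        dt = ts.regular_dt()
    if not np.isfinite(dt) or dt <= 0:
        raise ValueError(f"dt must be a positive real, got {dt}")
    k = dt * (flat @ flat.T)
    return KernelMatrix(k, list(ts.individual_ids), _meta(ts, "flin", dt=float(dt)))


def frbf_multivariate(ts: TimeSeriesTable, gamma: float) -> KernelMatrix:
    """Multivariate discrete functional RBF kernel matrix.

    Product over taxa of the per-taxon discrete RBF kernels — one shared
    bandwidth gamma — which collapses to an RBF kernel on the flattened
    matrix; the diagonal is identically 1.
    """
    if not np.isfinite(gamma) or gamma <= 0:
        raise ValueError(f"gamma must be a positive real, got {gamma}")
    flat = _flat(ts)
    ts.regular_dt()  # validates the common grid even though gamma absorbs dt
    d2 = squareform(pdist(flat, metric="sqeuclidean"))
    k = np.exp(-gamma * d2)
    np.fill_diagonal(k, 1.0)
    return KernelMatrix(k, list(ts.individual_ids), _meta(ts, "frbf", gamma=float(gamma)))
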