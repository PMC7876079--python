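"""Sample-level kernels for abundance tables and kernel-matrix utilities.

Four kernels are provided.  Two are compositional (they act on the clr
transform and are therefore invariant to library size):

* compositional linear ``cLin(x, y) = clr(x) . clr(y)``
* Aitchison RBF ``cRBF(x, y) = exp(-gamma ||clr(x) - clr(y)||^2)``

and two act on (normalized) abundances directly:

* Jensen-Shannon kernel ``JSK(x, y) = 1 - JS(x, y)`` (natural log), for
  relative frequencies; bounded in ``[1 - ln 2, 1]``
* quantitative Jaccard (Ruzicka) ``qJac(x, y) = sum_k min / sum_k max``,
  bounded in ``[0, 1]`` and untroubled by zeros.

All of them produce N x N positive semi-definite kernel matrices in
O(N^2 D) time; the same matrix feeds both the supervised (SVM) and the
unsupervised (kernel PCA) analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.linalg import eigvalsh
from scipy.spatial.distance import pdist, squareform

from .preprocess import clr_transform
from .tables import AbundanceTable

__all__ = [
    "KernelMatrix",
    "PSDReport",
    "clin_kernel",
    "crbf_kernel",
    "jsk_kernel",
    "qjac_kernel",
    "center_kernel",
    "cosine_normalize_kernel",
    "check_psd",
    "kernel_matrix_similarity",
    "aitchison_sq_distances",
]

_SYM_TOL = 1e-10


@dataclass
class KernelMatrix:
    """N x N symmetric PSD kernel matrix with aligned sample identifiers.

    ``meta`` records provenance: kernel name, hyperparameters and the
    preprocessing that produced the features.
    """

    values: np.ndarray
    sample_ids: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("kernel matrix must be square")
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(self.sample_ids) != self.values.shape[0]:
            raise ValueError("sample_ids length does not match matrix dimension")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample_ids in kernel matrix")
        scale = max(1.0, float(np.max(np.abs(self.values))) if self.values.size else 1.0)
        dev = float(np.max(np.abs(self.values - self.values.T))) if self.values.size else 0.0
        if dev > _SYM_TOL * scale:
            raise ValueError(
                f"kernel matrix is not symmetric (max deviation {dev:.3g})"
            )
        # remove the residual rounding asymmetry once and for all
        self.values = (self.values + self.values.T) / 2.0

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def aligned_with(self, other: "KernelMatrix") -> bool:
        return self.sample_ids == other.sample_ids


@dataclass
class PSDReport:
    """Outcome of a positive semi-definiteness check."""

    symmetric: bool
    symmetry_deviation: float
    min_eigenvalue: float
    max_eigenvalue: float
    tol: float

    @property
    def passed(self) -> bool:
        return self.symmetric and self.min_eigenvalue >= -self.tol * max(
            self.max_eigenvalue, self.tol
        )


def _table_meta(table: AbundanceTable) -> dict:
    return {"preprocessing": list(table.provenance)}


def clin_kernel(table: AbundanceTable) -> KernelMatrix:
    """Compositional linear kernel: Gram matrix of the clr-transformed rows.

    The linear structure is what later allows microbial signatures to be
    read off the SVM hyperplane.
    """
    clr = clr_transform(table)
    k = clr @ clr.T
    meta = _table_meta(table) | {"name": "clin"}
    return KernelMatrix(k, list(table.sample_ids), meta)


def aitchison_sq_distances(table: AbundanceTable) -> np.ndarray:
    """Pairwise squared Aitchison distances (squared Euclidean on clr rows).

    Useful to cache when scanning several RBF bandwidths: the cRBF matrix
    for any gamma is ``exp(-gamma * D2)``.
    """
    clr = clr_transform(table)
    return squareform(pdist(clr, metric="sqeuclidean"))


def crbf_kernel(table: AbundanceTable, gamma: float) -> KernelMatrix:
    """Aitchison-RBF kernel: exp(-gamma * squared Aitchison distance)."""
    if not np.isfinite(gamma) or gamma <= 0:
        raise ValueError(f"gamma must be a positive real, got {gamma}")
    d2 = aitchison_sq_distances(table)
    k = np.exp(-gamma * d2)
    np.fill_diagonal(k, 1.0)
    meta = _table_meta(table) | {"name": "crbf", "gamma": float(gamma)}
    return KernelMatrix(k, list(table.sample_ids), meta)


def jsk_kernel(table: AbundanceTable) -> KernelMatrix:
    """Jensen-Shannon kernel: 1 minus the JS divergence (natural log).

    Defined for relative frequencies; a count table is closed to row
    proportions first (with a warning).  Zeros follow the convention
    ``0 * ln(0/a) = 0``.  Values lie in ``[1 - ln 2, 1]``.
    """
    if np.any(table.values < 0):
        raise ValueError("Jensen-Shannon kernel requires non-negative entries")
    if table.scale != "relative":
        warnings.warn(
            "Jensen-Shannon kernel is defined for relative frequencies; "
            "closing count rows to proportions",
            UserWarning,
            stacklevel=2,
        )
        table = table.to_relative()
    x = table.values
    n = x.shape[0]
    k = np.empty((n, n))
    with np.errstate(divide="ignore", invalid="ignore"):
        for i in range(n):
            xi = x[i]  # (D,)
            s = xi + x[i:]  # (n-i, D)
            ti = xi * np.log(np.where(xi > 0, 2.0 * xi / np.where(s > 0, s, 1.0), 1.0))
            tj = x[i:] * np.log(
                np.where(x[i:] > 0, 2.0 * x[i:] / np.where(s > 0, s, 1.0), 1.0)
            )
            js = 0.5 * (np.nan_to_num(ti).sum(axis=1) + np.nan_to_num(tj).sum(axis=1))
            k[i, i:] = 1.0 - js
            k[i:, i] = k[i, i:]
    np.fill_diagonal(k, 1.0)
    meta = _table_meta(table) | {"name": "jsk"}
    return KernelMatrix(k, list(table.sample_ids), meta)


def qjac_kernel(table: AbundanceTable) -> KernelMatrix:
    """Quantitative Jaccard (Ruzicka) kernel: sum of minima over sum of maxima.

    Handles zeros natively.  Uses the identity ``sum min = (s_i + s_j - L1)/2``
    and ``sum max = (s_i + s_j + L1)/2`` with L1 the cityblock distance, so
    the whole matrix reduces to one pairwise-distance computation.
    """
    x = table.values
    if np.any(x < 0):
        raise ValueError("quantitative Jaccard kernel requires non-negative entries")
    s = x.sum(axis=1)
    l1 = squareform(pdist(x, metric="cityblock"))
    num = s[:, None] + s[None, :] - l1
    den = s[:, None] + s[None, :] + l1
    zero_pair = den == 0  # both rows entirely zero
    if np.any(zero_pair):
        warnings.warn(
            "pairs of all-zero samples: quantitative Jaccard set to 1 by convention",
            UserWarning,
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        k = np.where(zero_pair, 2.0, num) / np.where(zero_pair, 2.0, den)
    np.fill_diagonal(k, 1.0)
    meta = _table_meta(table) | {"name": "qjac"}
    return KernelMatrix(k, list(table.sample_ids), meta)


def _center_values(values: np.ndarray) -> np.ndarray:
    row = values.mean(axis=1, keepdims=True)
    col = values.mean(axis=0, keepdims=True)
    grand = values.mean()
    return values - row - col + grand


def center_kernel(K: KernelMatrix) -> KernelMatrix:
    """Double-center a kernel matrix (feature-space mean removal).

    Equivalent to ``J K J`` with ``J = I - ones/N``; required before the
    eigendecomposition in kernel PCA.
    """
    meta = dict(K.meta) | {"centered": True}
    return KernelMatrix(_center_values(K.values), list(K.sample_ids), meta)


def cosine_normalize_kernel(K: KernelMatrix) -> KernelMatrix:
    """Normalize to unit diagonal: K'[i,j] = K[i,j] / sqrt(K[i,i] K[j,j]).

    Puts kernels of different scales on a comparable footing before they
    are combined by multiple kernel learning.
    """
    diag = np.diag(K.values).copy()
    bad = np.where(diag <= 0)[0]
    if bad.size:
        names = [K.sample_ids[i] for i in bad[:5]]
        raise ValueError(f"non-positive kernel diagonal for samples {names}")
    root = np.sqrt(diag)
    values = K.values / np.outer(root, root)
    np.fill_diagonal(values, 1.0)
    meta = dict(K.meta) | {"cosine_normalized": True}
    return KernelMatrix(values, list(K.sample_ids), meta)


def check_psd(K: KernelMatrix | np.ndarray, tol: float = 1e-8) -> PSDReport:
    """Report symmetry deviation and the extreme eigenvalues of a matrix.

    Passes iff the matrix is symmetric within ``tol`` and its minimum
    eigenvalue is >= ``-tol`` times the maximum eigenvalue.
    """
    values = K.values if isinstance(K, KernelMatrix) else np.asarray(K, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError(f"matrix must be square, got shape {values.shape}")
    dev = float(np.max(np.abs(values - values.T))) if values.size else 0.0
    sym = dev <= tol * max(1.0, float(np.max(np.abs(values))) if values.size else 1.0)
    eigs = eigvalsh((values + values.T) / 2.0)
    return PSDReport(
        symmetric=sym,
        symmetry_deviation=dev,
        min_eigenvalue=float(eigs[0]),
        max_eigenvalue=float(eigs[-1]),
        tol=float(tol),
    )


def kernel_matrix_similarity(Ks: Sequence[KernelMatrix]) -> np.ndarray:
    """Pairwise Frobenius cosine between centered kernel matrices.

    Used to compare the views different body sites (or different kernels)
    give of the same individuals; diagonal 1, values in [-1, 1].
    """
    if len(Ks) == 0:
        raise ValueError("need at least one kernel matrix")
    ids = Ks[0].sample_ids
    for K in Ks[1:]:
        if K.sample_ids != ids:
            raise ValueError("kernel matrices have mismatched sample_ids")
    flats = [_center_values(K.values).ravel() for K in Ks]
    m = len(flats)
    sim = np.eye(m)
    norms = [np.linalg.norm(f) for f in flats]
    for a in range(m):
        for b in range(a + 1, m):
            denom = norms[a] * norms[b]
            sim[a, b] = sim[b, a] = float(flats[a] @ flats[b] / denom) if denom > 0 else 0.0
    return sim
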