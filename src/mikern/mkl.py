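"""Multiple kernel learning: consensus kernels for spatially structured samples.

When the same individuals are sampled at several sites (or through
several omics), each site yields its own kernel matrix K_1..K_M over the
identical individuals.  A consensus matrix K* = sum_z beta_z K_z with
beta_z >= 0 integrates them while remaining a valid kernel.  The weights
are found either

* supervised — a grid search on the unit simplex scored by repeated
  cross-validated SVM performance on K*(beta); or
* unsupervised — the beta maximizing the average Frobenius-cosine
  similarity of K* with the individual matrices, i.e. the leading
  eigenvector of their M x M similarity matrix.

Spatio-temporal designs compose: a functional kernel per site handles
time, MKL then integrates across sites.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.linalg import eigh

from .kernels import (
    KernelMatrix,
    cosine_normalize_kernel,
    kernel_matrix_similarity,
)
from .learn import CVConfig, _derive_seed, inner_cv_score
from .longitudinal import flin_multivariate, frbf_multivariate
from .tables import TimeSeriesTable

__all__ = [
    "KernelBank",
    "MKLWeights",
    "mkl_combine",
    "mkl_optimize_supervised",
    "consensus_unsupervised",
    "spatiotemporal_kernel",
    "simplex_grid",
]

_TIE_TOL = 1e-12


@dataclass
class KernelBank:
    """M kernel matrices over identical, identically ordered samples."""

    matrices: list[KernelMatrix]
    labels: list[str]

    def __post_init__(self) -> None:
        if len(self.matrices) < 1:
            raise ValueError("a kernel bank needs at least one matrix")
        if len(self.labels) != len(self.matrices):
            raise ValueError("labels must match the number of matrices")
        ids = self.matrices[0].sample_ids
        for lab, K in zip(self.labels, self.matrices):
            if K.sample_ids != ids:
                raise ValueError(
                    f"kernel matrix {lab!r} is not aligned with the others"
                )

    @property
    def n_kernels(self) -> int:
        return len(self.matrices)

    @property
    def sample_ids(self) -> list[str]:
        return self.matrices[0].sample_ids

    def cosine_normalized(self) -> "KernelBank":
        return KernelBank([cosine_normalize_kernel(K) for K in self.matrices],
                          list(self.labels))


@dataclass
class MKLWeights:
    """Non-negative combination coefficients beta_1..beta_M."""

    betas: np.ndarray
    normalized: bool = True

    def __post_init__(self) -> None:
        self.betas = np.asarray(self.betas, dtype=float)
        if self.betas.ndim != 1:
            raise ValueError("betas must be a 1-D vector")
        if np.any(self.betas < 0):
            raise ValueError("betas must be non-negative")
        if self.normalized and abs(self.betas.sum() - 1.0) > 1e-10:
            raise ValueError("normalized betas must sum to 1")


def mkl_combine(bank: KernelBank, w: MKLWeights) -> KernelMatrix:
    """Consensus kernel K* = sum_z beta_z K_z (PSD-preserving)."""
    betas = w.betas
    if betas.size != bank.n_kernels:
        raise ValueError(
            f"{betas.size} betas for {bank.n_kernels} kernel matrices"
        )
    if np.all(betas == 0):
        raise ValueError("all-zero betas give a degenerate consensus kernel")
    values = sum(b * K.values for b, K in zip(betas, bank.matrices))
    meta = {
        "name": "mkl",
        "components": list(bank.labels),
        "betas": [float(b) for b in betas],
    }
    return KernelMatrix(values, bank.sample_ids, meta)


def simplex_grid(m: int, resolution: int) -> np.ndarray:
    """All beta vectors with entries i/resolution summing to 1 (lattice simplex)."""
    if m < 1 or resolution < 1:
        raise ValueError("need m >= 1 and resolution >= 1")
    points = []
    for comp in itertools.combinations_with_replacement(range(m), resolution):
        beta = np.zeros(m)
        for z in comp:
            beta[z] += 1.0 / resolution
        points.append(beta)
    return np.unique(np.round(np.array(points), 12), axis=0)


def _entropy(beta: np.ndarray) -> float:
    p = beta[beta > 0]
    return float(-(p * np.log(p)).sum())


def mkl_optimize_supervised(
    bank: KernelBank,
    y,
    task: str = "classification",
    grid_resolution: int | None = None,
    cv: CVConfig | None = None,
    cost_grid: Sequence[float] = (0.01, 0.1, 1.0, 10.0, 100.0),
) -> tuple[MKLWeights, float, float]:
    """Supervised MKL: simplex grid search on beta scored by inner-CV SVM.

    Matrices are cosine-normalized before combination so betas are
    comparable across kernels of different scales.  Every candidate beta
    (including the one-hot corners, so the consensus can never score
    worse than the best single kernel on this grid) is evaluated jointly
    with the SVM cost by repeated k-fold cross-validation; ties are broken
    toward the most uniform beta, then toward the smaller cost.

    Returns ``(weights, best_cost, best_cv_score)``.
    """
    cv = cv or CVConfig()
    y = np.asarray(y)
    if y.shape[0] != len(bank.sample_ids):
        raise ValueError("labels are not aligned with the kernel bank")
    m = bank.n_kernels
    if m == 1:
        return MKLWeights(np.array([1.0])), float(sorted(cost_grid)[0]), np.nan
    if grid_resolution is None:
        grid_resolution = 10 if m <= 3 else 4
    normed = bank.cosine_normalized()
    stacked = np.stack([K.values for K in normed.matrices])  # M x N x N
    costs = sorted(float(c) for c in cost_grid)
    seed = _derive_seed(cv.seed, 7)
    evaluated: list[tuple[float, np.ndarray, float]] = []
    for beta in simplex_grid(m, grid_resolution):
        K = np.tensordot(beta, stacked, axes=1)
        for cost in costs:
            s = inner_cv_score(K, y, task, cost, cv.inner_folds, cv.inner_repeats, seed)
            evaluated.append((s, beta, cost))
    best_score = max(s for s, _, _ in evaluated)
    # tie-break among equal scorers: most uniform beta, then smaller cost
    tied = [(beta, cost) for s, beta, cost in evaluated if s >= best_score - _TIE_TOL]
    tied.sort(key=lambda bc: (-_entropy(bc[0]), bc[1]))
    beta, cost = tied[0]
    return MKLWeights(beta), float(cost), float(best_score)


def consensus_unsupervised(bank: KernelBank) -> MKLWeights:
    """Unsupervised consensus weights maximizing average kernel similarity.

    The average Frobenius-cosine similarity of K*(beta) with the bank is
    a Rayleigh quotient of the M x M similarity matrix of the (centered,
    cosine-normalized) kernels, so the optimal beta is its leading
    eigenvector — entrywise non-negative by Perron-Frobenius whenever the
    similarity matrix is, and normalized here to sum to 1.
    """
    m = bank.n_kernels
    if m < 2:
        return MKLWeights(np.ones(m))
    sim = kernel_matrix_similarity(bank.cosine_normalized().matrices)
    _, vec = eigh(sim, subset_by_index=[m - 1, m - 1])
    beta = vec[:, 0]
    if beta.sum() < 0:
        beta = -beta
    if np.any(beta < -1e-12):
        warnings.warn(
            "leading eigenvector has negative entries (negatively correlated "
            "kernels); clipping at zero",
            UserWarning,
            stacklevel=2,
        )
    beta = beta.clip(min=0.0)
    return MKLWeights(beta / beta.sum())


def spatiotemporal_kernel(
    series_by_site: Mapping[str, TimeSeriesTable],
    kernel: str = "frbf",
    gamma: float | None = None,
    weights: MKLWeights | str = "consensus",
    y=None,
    task: str = "classification",
    cv: CVConfig | None = None,
) -> tuple[KernelMatrix, MKLWeights]:
    """Temporal kernels per site, then spatial integration by MKL.

    Each site's time series is turned into a longitudinal kernel matrix
    (``flin`` or ``frbf``); the per-site matrices are then combined into a
    consensus kernel.  ``weights`` may be explicit :class:`MKLWeights`,
    ``"consensus"`` (unsupervised) or ``"optimize"`` (supervised; requires
    ``y``).
    """
    if not series_by_site:
        raise ValueError("need at least one site")
    sites = list(series_by_site.keys())
    ids = series_by_site[sites[0]].individual_ids
    missing = {
        site: sorted(set(ids) ^ set(ts.individual_ids))
        for site, ts in series_by_site.items()
        if ts.individual_ids != ids
    }
    if missing:
        raise ValueError(f"individuals unmatched across sites: {missing}")
    if kernel == "flin":
        mats = [flin_multivariate(series_by_site[s]) for s in sites]
    elif kernel == "frbf":
        if gamma is None:
            raise ValueError("frbf requires gamma")
        mats = [frbf_multivariate(series_by_site[s], gamma) for s in sites]
    else:
        raise ValueError(f"kernel must be 'flin' or 'frbf', got {kernel!r}")
    if len(sites) == 1:  # single site: the longitudinal kernel itself, untouched
        return mats[0], MKLWeights(np.array([1.0]))
    bank = KernelBank(mats, sites)
    if isinstance(weights, MKLWeights):
        w = weights
    elif weights == "consensus":
        w = consensus_unsupervised(bank)
    elif weights == "optimize":
        if y is None:
            raise ValueError("supervised weight optimization requires y")
        w, _, _ = mkl_optimize_supervised(bank, y, task=task, cv=cv)
    else:
        raise ValueError("weights must be MKLWeights, 'consensus' or 'optimize'")
    combined = mkl_combine(bank.cosine_normalized(), w)
    return combined, w
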