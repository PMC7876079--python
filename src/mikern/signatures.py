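"""Microbial-signature retrieval from linear-kernel SVM hyperplanes.

For a linear kernel the SVM decision function is an explicit hyperplane
``w . phi(x) + b`` whose normal vector w lives in feature space — here
the clr-transformed abundances (compositional linear kernel) or the
flattened taxon x time clr trajectories (discrete functional linear
kernel).  A taxon orthogonal to the hyperplane is maximally informative,
so the importance of taxon k is w_k^2, reported as relative values
summing to 1.  Signatures are linear-kernel-only: non-linear kernels
have no explicit w.

Aggregation rules:

* spatial — a taxon's global importance across sites is the beta-weighted
  sum of its per-site (unnormalized) importances, using the MKL weights;
* longitudinal — a taxon's importance is the sum of its squared weights
  over the T time points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .learn import TrainedModel
from .mkl import MKLWeights

__all__ = [
    "Signature",
    "hyperplane_weights",
    "signature_from_clin_svm",
    "signature_spatial_aggregate",
    "signature_longitudinal",
    "select_top_fraction",
    "average_signatures",
]

_LINEAR_KERNELS = {"clin", "flin", "linear"}


@dataclass
class Signature:
    """Per-taxon relative importances (non-negative, summing to 1).

    ``raw`` keeps the unnormalized squared weights so that spatial
    aggregation can weight sites before renormalizing; ``stderr`` holds
    across-replicate standard errors when the signature is an average.
    """

    taxon_ids: list[str]
    importances: np.ndarray
    mode: str = "single"
    raw: np.ndarray | None = None
    stderr: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.importances = np.asarray(self.importances, dtype=float)
        if self.importances.ndim != 1 or len(self.taxon_ids) != self.importances.size:
            raise ValueError("importances must be 1-D and match taxon_ids")
        if np.any(self.importances < 0):
            raise ValueError("importances must be non-negative")
        if abs(self.importances.sum() - 1.0) > 1e-10:
            raise ValueError("importances must sum to 1")

    def ranking(self) -> list[tuple[str, float]]:
        """Taxa sorted by decreasing importance (ties by taxon id)."""
        order = sorted(range(len(self.taxon_ids)),
                       key=lambda i: (-self.importances[i], self.taxon_ids[i]))
        return [(self.taxon_ids[i], float(self.importances[i])) for i in order]


def _require_linear(model: TrainedModel) -> None:
    name = model.kernel_meta.get("name")
    if name not in _LINEAR_KERNELS:
        raise ValueError(
            f"signatures require a linear-type kernel (cLin/fLin); the model was "
            f"trained with {name!r} — non-linear kernels have no explicit hyperplane"
        )


def hyperplane_weights(model: TrainedModel, features: np.ndarray) -> np.ndarray:
    """Hyperplane normal w from the dual expansion over support samples.

    ``features`` must be the exact feature matrix (training-sample order)
    used to build the training kernel.  For classification the stored dual
    coefficients are alpha_i * y_i; for regression alpha_i - alpha_i^*.
    Either way w = sum_i coef_i * features_i.
    """
    _require_linear(model)
    features = np.asarray(features, dtype=float)
    if features.shape[0] != len(model.sample_ids):
        raise ValueError(
            f"feature matrix has {features.shape[0]} rows but the model was "
            f"trained on {len(model.sample_ids)} samples"
        )
    dual = model.dual_coef_
    if dual.shape[0] != 1:
        raise ValueError("signatures are defined for binary classification or regression")
    return dual[0] @ features[model.support_]


def signature_from_clin_svm(model: TrainedModel, clr_features: np.ndarray,
                            taxon_ids: Sequence[str]) -> Signature:
    """Signature of a compositional-linear SVM: relative (w_k)^2 per taxon.

    Importances are to be read on the clr scale — they quantify how much
    each log-ratio coordinate orients the separating hyperplane.
    """
    w = hyperplane_weights(model, clr_features)
    if w.size != len(taxon_ids):
        raise ValueError("taxon_ids do not match the feature dimension")
    raw = w**2
    total = raw.sum()
    if total == 0:
        raise ValueError("degenerate model: all hyperplane weights are zero")
    return Signature(
        taxon_ids=list(taxon_ids),
        importances=raw / total,
        mode="single",
        raw=raw,
        provenance={"kernel": model.kernel_meta.get("name"), "cost": model.cost},
    )


def signature_spatial_aggregate(site_signatures: Sequence[Signature],
                                betas: MKLWeights) -> Signature:
    """Global importances across sites: beta-weighted sum of per-site (w_k)^2.

    Weighting the unnormalized importances by beta_z is algebraically the
    same as scaling each site's feature map by sqrt(beta_z) before reading
    off the hyperplane.  Sites with different taxon sets are merged on the
    union (absent taxa count 0) with a warning.  Normalization to relative
    values happens after aggregation.
    """
    if len(site_signatures) != betas.betas.size:
        raise ValueError("one beta per site signature is required")
    taxa_sets = [tuple(s.taxon_ids) for s in site_signatures]
    if len(set(taxa_sets)) > 1:
        warnings.warn(
            "sites have different taxon sets; aggregating on the union with zero fill",
            UserWarning,
            stacklevel=2,
        )
    union = sorted(set().union(*(set(t) for t in taxa_sets)))
    index = {t: i for i, t in enumerate(union)}
    total = np.zeros(len(union))
    for sig, beta in zip(site_signatures, betas.betas):
        raw = sig.raw if sig.raw is not None else sig.importances
        for t, v in zip(sig.taxon_ids, raw):
            total[index[t]] += beta * v
    if total.sum() == 0:
        raise ValueError("aggregated importances are all zero")
    return Signature(
        taxon_ids=union,
        importances=total / total.sum(),
        mode="spatial",
        raw=total,
        provenance={"betas": [float(b) for b in betas.betas]},
    )


def signature_longitudinal(model: TrainedModel, flattened_features: np.ndarray,
                           taxon_ids: Sequence[str], n_timepoints: int) -> Signature:
    """Signature of a discrete functional-linear SVM.

    ``flattened_features`` is the N x (D*T) taxon-major matrix the fLin
    kernel was built from; the importance of taxon k sums the squared
    hyperplane weights of its T time coordinates.
    """
    w = hyperplane_weights(model, flattened_features)
    d = len(taxon_ids)
    if w.size != d * n_timepoints:
        raise ValueError(
            f"feature layout mismatch: {w.size} weights cannot be reshaped to "
            f"{d} taxa x {n_timepoints} time points"
        )
    raw = (w.reshape(d, n_timepoints) ** 2).sum(axis=1)
    total = raw.sum()
    if total == 0:
        raise ValueError("degenerate model: all hyperplane weights are zero")
    return Signature(
        taxon_ids=list(taxon_ids),
        importances=raw / total,
        mode="longitudinal",
        raw=raw,
        provenance={"kernel": model.kernel_meta.get("name"),
                    "n_timepoints": int(n_timepoints), "cost": model.cost},
    )


def select_top_fraction(sig: Signature, fraction: float) -> tuple[Signature, float]:
    """Keep the top ceil(fraction * D) taxa; report their cumulative share.

    Ties at the cutoff are broken by taxon id (lexical) for determinism.
    The subset's importances are renormalized to sum to 1; the second
    return value is the kept taxa's cumulative share of the original
    total importance.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError(f"fraction must lie in (0, 1], got {fraction}")
    d = len(sig.taxon_ids)
    keep = int(np.ceil(fraction * d))
    ranked = sig.ranking()[:keep]
    share = float(sum(v for _, v in ranked))
    taxa = [t for t, _ in ranked]
    vals = np.array([v for _, v in ranked])
    subset = Signature(
        taxon_ids=taxa,
        importances=vals / vals.sum(),
        mode=sig.mode,
        raw=vals,
        provenance=dict(sig.provenance) | {"top_fraction": float(fraction),
                                           "cumulative_share": share},
    )
    return subset, share


def average_signatures(signatures: Sequence[Signature]) -> Signature:
    """Mean of per-replicate relative importances, with standard errors.

    Replicated evaluations produce one signature per train/test split;
    reporting their mean (renormalized) with across-replicate standard
    errors mirrors how signature bar plots with error bars are built.
    """
    if not signatures:
        raise ValueError("need at least one signature")
    taxa = signatures[0].taxon_ids
    for s in signatures[1:]:
        if s.taxon_ids != taxa:
            raise ValueError("signatures must share identical taxon_ids")
    mat = np.stack([s.importances for s in signatures])
    mean = mat.mean(axis=0)
    stderr = mat.std(axis=0, ddof=1) / np.sqrt(mat.shape[0]) if mat.shape[0] > 1 \
        else np.zeros_like(mean)
    return Signature(
        taxon_ids=list(taxa),
        importances=mean / mean.sum(),
        mode=signatures[0].mode,
        raw=mean,
        stderr=stderr,
        provenance={"n_replicates": len(signatures)},
    )
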