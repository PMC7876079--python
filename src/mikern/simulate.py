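"""Synthetic microbiome data with planted, recoverable structure.

The generator emulates the three study designs the framework targets:

* single-point tables with a handful of group-discriminating taxa,
* multi-site tables of the same individuals (some sites informative,
  some pure noise),
* multi-time-point tables where only selected time points separate the
  classes.

Compositions are logistic-normal: a latent multivariate-normal vector on
the clr scale is pushed through a softmax, so planted clr-scale mean
shifts are *exactly* the effects the compositional kernels and linear
signatures should recover — which makes recovery a well-posed test.
Counts are drawn multinomially at log-normally distributed library
sizes (order-of-magnitude spread, as in real sequencing runs), and
sparsity beyond the natural sampling zeros is added by thinning entries
to a target zero fraction.

Every generator returns the ground truth (informative taxa, sites or
time points) next to the data, and the seed fully determines the output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .tables import AbundanceTable, TimeSeriesTable

__all__ = [
    "SimulationConfig",
    "SimulationResult",
    "simulate_single_point",
    "simulate_multisite",
    "simulate_longitudinal",
]


@dataclass
class SimulationConfig:
    """Knobs of the synthetic-data generator.

    ``effect_size`` is the clr-scale separation between class means on an
    informative taxon (each class is shifted by +/- effect_size/2).
    ``informative_timepoints`` uses 1-based indices into the time grid;
    ``informative_sites`` are 0-based site indices (None = every site).
    ``library_size_mean`` is the median library size; ``library_size_sigma``
    the log-scale spread of the log-normal (1.0 spans roughly two orders
    of magnitude across samples).
    """

    n_individuals: int = 150
    n_taxa: int = 200
    n_informative: int = 10
    effect_size: float = 2.0
    latent_sd: float = 1.0
    baseline_sd: float = 1.0
    library_size_mean: float = 1e4
    library_size_sigma: float = 1.0
    zero_fraction: float = 0.1
    n_sites: int = 2
    site_correlation: float = 0.5
    informative_sites: Sequence[int] | None = None
    n_timepoints: int = 3
    informative_timepoints: Sequence[int] = (3,)
    informative_indices: Sequence[int] | None = None
    task: str = "classification"
    target_noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative > self.n_taxa:
            raise ValueError("n_informative cannot exceed n_taxa")
        if not (0.0 <= self.zero_fraction < 1.0):
            raise ValueError("zero_fraction must lie in [0, 1)")
        if self.task not in ("classification", "regression"):
            raise ValueError("task must be 'classification' or 'regression'")
        bad = [t for t in self.informative_timepoints
               if not (1 <= t <= self.n_timepoints)]
        if bad:
            raise ValueError(
                f"informative_timepoints {bad} outside 1..{self.n_timepoints}"
            )
        if self.informative_indices is not None:
            if len(self.informative_indices) != self.n_informative:
                raise ValueError("informative_indices must have n_informative entries")
            if any(not (0 <= i < self.n_taxa) for i in self.informative_indices):
                raise ValueError("informative_indices out of range")
        if not (0.0 <= self.site_correlation <= 1.0):
            raise ValueError("site_correlation must lie in [0, 1]")


@dataclass
class SimulationResult:
    """Synthetic dataset plus its ground truth."""

    table: AbundanceTable | None
    tables_by_site: dict[str, AbundanceTable] | None
    timeseries: TimeSeriesTable | None
    y: np.ndarray
    informative_taxa: np.ndarray  # column indices carrying signal
    true_signature: np.ndarray  # relative importances (uniform on planted taxa)
    informative_sites: list[int] | None = None
    informative_timepoints: list[int] | None = None
    config: SimulationConfig | None = None


def _rng(cfg: SimulationConfig, *stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, *stream]))


def _informative(cfg: SimulationConfig) -> np.ndarray:
    if cfg.informative_indices is not None:
        return np.asarray(sorted(cfg.informative_indices), dtype=int)
    rng = _rng(cfg, 0)
    return np.sort(rng.choice(cfg.n_taxa, size=cfg.n_informative, replace=False))


def _labels(cfg: SimulationConfig) -> np.ndarray:
    """Balanced binary class labels in {0, 1}, randomly ordered."""
    rng = _rng(cfg, 1)
    y = np.zeros(cfg.n_individuals, dtype=int)
    y[: cfg.n_individuals // 2] = 1
    return rng.permutation(y)


def _true_signature(cfg: SimulationConfig, informative: np.ndarray) -> np.ndarray:
    sig = np.zeros(cfg.n_taxa)
    sig[informative] = 1.0 / informative.size if informative.size else 0.0
    return sig


def _counts_from_latent(cfg: SimulationConfig, latent: np.ndarray,
                        rng: np.random.Generator) -> np.ndarray:
    """Softmax the latent clr-scale matrix and draw multinomial counts."""
    shifted = latent - latent.max(axis=1, keepdims=True)
    expl = np.exp(shifted)
    probs = expl / expl.sum(axis=1, keepdims=True)
    sizes = rng.lognormal(mean=np.log(cfg.library_size_mean),
                          sigma=cfg.library_size_sigma, size=latent.shape[0])
    sizes = np.maximum(sizes.astype(int), 100)
    counts = np.empty_like(latent)
    for i in range(latent.shape[0]):
        counts[i] = rng.multinomial(sizes[i], probs[i])
    return counts


def _thin_to_zero_fraction(cfg: SimulationConfig, counts: np.ndarray,
                           rng: np.random.Generator) -> np.ndarray:
    """Randomly zero entries until the target sparsity is reached.

    The most abundant taxon of each sample is protected so no sample
    becomes all-zero.  If sampling zeros already exceed the target the
    table is returned untouched.
    """
    target = cfg.zero_fraction
    natural = float(np.mean(counts == 0))
    if target <= natural:
        return counts
    p_thin = (target - natural) / (1.0 - natural)
    mask = (counts > 0) & (rng.random(counts.shape) < p_thin)
    mask[np.arange(counts.shape[0]), counts.argmax(axis=1)] = False
    out = counts.copy()
    out[mask] = 0.0
    return out


def _ids(prefix: str, n: int) -> list[str]:
    width = len(str(n))
    return [f"{prefix}{i:0{width}d}" for i in range(1, n + 1)]


def _class_shift(cfg: SimulationConfig, y: np.ndarray,
                 informative: np.ndarray) -> np.ndarray:
    """N x D clr-scale mean-shift matrix: +/- effect_size/2 by class."""
    shift = np.zeros((cfg.n_individuals, cfg.n_taxa))
    signs = np.where(y == 1, 0.5, -0.5) * cfg.effect_size
    shift[:, informative] = signs[:, None]
    return shift


def simulate_single_point(cfg: SimulationConfig) -> SimulationResult:
    """One abundance table with planted group-discriminating taxa.

    Classification: informative taxa receive opposite clr-scale mean
    shifts in the two classes.  Regression: a continuous target is a
    linear function of the informative latent coordinates plus noise
    (emulating an environmental-gradient task such as pH prediction).
    """
    informative = _informative(cfg)
    rng = _rng(cfg, 2)
    baseline = rng.normal(0.0, cfg.baseline_sd, size=cfg.n_taxa)
    latent = rng.normal(0.0, cfg.latent_sd, size=(cfg.n_individuals, cfg.n_taxa))
    if cfg.task == "classification":
        y = _labels(cfg)
        latent = latent + _class_shift(cfg, y, informative)
    else:
        contrib = latent[:, informative].sum(axis=1) / np.sqrt(max(informative.size, 1))
        y = cfg.effect_size * contrib + rng.normal(0.0, cfg.target_noise_sd,
                                                   size=cfg.n_individuals)
    counts = _counts_from_latent(cfg, latent + baseline, rng)
    counts = _thin_to_zero_fraction(cfg, counts, rng)
    table = AbundanceTable(counts, _ids("S", cfg.n_individuals), _ids("taxon", cfg.n_taxa),
                           scale="counts", provenance=["simulated single-point table"])
    return SimulationResult(
        table=table, tables_by_site=None, timeseries=None, y=y,
        informative_taxa=informative,
        true_signature=_true_signature(cfg, informative),
        config=cfg,
    )


def simulate_multisite(cfg: SimulationConfig) -> SimulationResult:
    """Tables from several sites over the same individuals.

    A shared per-individual latent component (weight sqrt(rho), with rho
    the site correlation) plus site-specific innovations; class signal is
    planted only in ``informative_sites``.  With rho = 1 all sites share
    both latents and count draws, hence identical tables.
    """
    if cfg.n_sites < 2:
        raise ValueError("multisite simulation needs n_sites >= 2")
    informative = _informative(cfg)
    inf_sites = (list(range(cfg.n_sites)) if cfg.informative_sites is None
                 else sorted(int(s) for s in cfg.informative_sites))
    y = _labels(cfg)
    rho = cfg.site_correlation
    shared_rng = _rng(cfg, 3)
    shared = shared_rng.normal(0.0, cfg.latent_sd,
                               size=(cfg.n_individuals, cfg.n_taxa))
    baseline = shared_rng.normal(0.0, cfg.baseline_sd, size=cfg.n_taxa)
    shift = _class_shift(cfg, y, informative)
    tables: dict[str, AbundanceTable] = {}
    for s in range(cfg.n_sites):
        # rho == 1: reuse stream 0 for every site so draws coincide exactly
        stream = 0 if rho == 1.0 else s
        rng = _rng(cfg, 4, stream)
        own = rng.normal(0.0, cfg.latent_sd, size=(cfg.n_individuals, cfg.n_taxa))
        latent = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * own
        if s in inf_sites:
            latent = latent + shift
        counts = _counts_from_latent(cfg, latent + baseline, rng)
        counts = _thin_to_zero_fraction(cfg, counts, rng)
        tables[f"site{s + 1}"] = AbundanceTable(
            counts, _ids("S", cfg.n_individuals), _ids("taxon", cfg.n_taxa),
            scale="counts", provenance=[f"simulated multi-site table, site {s + 1}"])
    return SimulationResult(
        table=None, tables_by_site=tables, timeseries=None, y=y,
        informative_taxa=informative,
        true_signature=_true_signature(cfg, informative),
        informative_sites=inf_sites,
        config=cfg,
    )


def simulate_longitudinal(cfg: SimulationConfig) -> SimulationResult:
    """Per-individual trajectories where only some time points carry signal.

    Each individual has a latent baseline shared across time plus
    time-specific innovations (an equicorrelated trajectory); the class
    shift is applied only at ``informative_timepoints``, so the remaining
    time points are exchangeable between classes.
    """
    if cfg.n_timepoints < 2:
        raise ValueError("longitudinal simulation needs n_timepoints >= 2")
    informative = _informative(cfg)
    inf_times = sorted(int(t) for t in cfg.informative_timepoints)
    y = _labels(cfg)
    rng = _rng(cfg, 5)
    baseline = rng.normal(0.0, cfg.baseline_sd, size=cfg.n_taxa)
    person = rng.normal(0.0, cfg.latent_sd,
                        size=(cfg.n_individuals, cfg.n_taxa))  # shared across time
    shift = _class_shift(cfg, y, informative)
    values = np.empty((cfg.n_individuals, cfg.n_taxa, cfg.n_timepoints))
    for t in range(cfg.n_timepoints):
        innov = rng.normal(0.0, cfg.latent_sd, size=(cfg.n_individuals, cfg.n_taxa))
        latent = (person + innov) / np.sqrt(2.0)
        if (t + 1) in inf_times:
            latent = latent + shift
        counts = _counts_from_latent(cfg, latent + baseline, rng)
        counts = _thin_to_zero_fraction(cfg, counts, rng)
        values[:, :, t] = counts
    ts = TimeSeriesTable(
        values=values,
        individual_ids=_ids("S", cfg.n_individuals),
        taxon_ids=_ids("taxon", cfg.n_taxa),
        times=np.arange(1.0, cfg.n_timepoints + 1.0),
        provenance=["simulated longitudinal table"],
    )
    return SimulationResult(
        table=None, tables_by_site=None, timeseries=ts, y=y,
        informative_taxa=informative,
        true_signature=_true_signature(cfg, informative),
        informative_timepoints=inf_times,
        config=cfg,
    )
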