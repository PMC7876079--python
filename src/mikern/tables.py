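"""In-memory containers for abundance data.

Microbiome abundance tables hold per-sample taxon counts (or relative
abundances) obtained from amplicon or shotgun sequencing.  The containers
here are deliberately light: a validated NumPy array plus sample/taxon
identifiers, with provenance carried along by the operations that
transform them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = ["AbundanceTable", "TimeSeriesTable"]

_REL_TOL = 1e-8


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        seen, dups = set(), []
        for i in ids:
            if i in seen:
                dups.append(i)
            seen.add(i)
        raise ValueError(f"duplicate {what}: {sorted(set(dups))}")
    return ids


@dataclass
class AbundanceTable:
    """Samples x taxa non-negative abundance matrix.

    Parameters
    ----------
    values : (N, D) array
        Read counts or relative abundances; all entries must be >= 0.
    sample_ids, taxon_ids : sequences of str
        Unique row / column identifiers.
    scale : {"counts", "relative"}
        On the ``relative`` scale every row must sum to 1 (tolerance 1e-8).
    provenance : list of str
        Record of preprocessing steps applied so far.
    """

    values: np.ndarray
    sample_ids: list[str]
    taxon_ids: list[str]
    scale: str = "counts"
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D samples x taxa matrix")
        self.sample_ids = _check_unique(self.sample_ids, "sample_ids")
        self.taxon_ids = _check_unique(self.taxon_ids, "taxon_ids")
        n, d = self.values.shape
        if len(self.sample_ids) != n or len(self.taxon_ids) != d:
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} sample_ids x {len(self.taxon_ids)} taxon_ids"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values contain NaN or infinity")
        if np.any(self.values < 0):
            raise ValueError("abundance values must be non-negative")
        if self.scale not in ("counts", "relative"):
            raise ValueError(f"scale must be 'counts' or 'relative', got {self.scale!r}")
        if self.scale == "relative":
            sums = self.values.sum(axis=1)
            bad = np.where(np.abs(sums - 1.0) > _REL_TOL)[0]
            if bad.size:
                names = [self.sample_ids[i] for i in bad[:5]]
                raise ValueError(f"relative-scale rows do not sum to 1: {names}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: np.ndarray, *, scale: str | None = None,
                    note: str | None = None) -> "AbundanceTable":
        """Copy of the table with new values and an appended provenance note."""
        prov = list(self.provenance) + ([note] if note else [])
        return replace(self, values=np.asarray(values, dtype=float),
                       scale=scale or self.scale, provenance=prov)

    def to_relative(self) -> "AbundanceTable":
        """Close each row to proportions (row sum 1)."""
        sums = self.values.sum(axis=1, keepdims=True)
        zero = np.where(sums.ravel() == 0)[0]
        if zero.size:
            names = [self.sample_ids[i] for i in zero]
            raise ValueError(f"cannot normalize all-zero samples: {names}")
        return self.with_values(self.values / sums, scale="relative",
                                note="closed to relative abundances")


@dataclass
class TimeSeriesTable:
    """Individuals x taxa x time points abundance array.

    ``values[i, k, t]`` is the abundance of taxon ``k`` in individual ``i``
    at time ``times[t]``.  ``observed`` (individuals x time points) marks
    which samples were actually collected; the discrete functional kernels
    require a fully observed common grid, the continuous ones tolerate
    missing points.
    """

    values: np.ndarray
    individual_ids: list[str]
    taxon_ids: list[str]
    times: np.ndarray
    observed: np.ndarray | None = None
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be individuals x taxa x time points")
        self.individual_ids = _check_unique(self.individual_ids, "individual_ids")
        self.taxon_ids = _check_unique(self.taxon_ids, "taxon_ids")
        self.times = np.asarray(self.times, dtype=float)
        n, d, t = self.values.shape
        if (len(self.individual_ids), len(self.taxon_ids), self.times.size) != (n, d, t):
            raise ValueError("ids/times do not match the values array shape")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        # values may be raw counts or clr-transformed (signed), so no sign check
        if self.observed is not None:
            self.observed = np.asarray(self.observed, dtype=bool)
            if self.observed.shape != (n, t):
                raise ValueError("observed mask must be individuals x time points")

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.values.shape[1]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[2]

    def has_missing(self) -> bool:
        return self.observed is not None and not bool(self.observed.all())

    def regular_dt(self) -> float:
        """Common grid spacing; refuses irregular grids.

        The discrete functional kernels are only defined on a shared,
        evenly spaced grid without missing samples; irregular designs must
        use the continuous (interpolating) kernels instead.
        """
        if self.has_missing():
            raise ValueError(
                "time series has missing points; use the continuous functional kernels"
            )
        if self.times.size == 1:
            return 1.0
        steps = np.diff(self.times)
        if np.max(steps) - np.min(steps) > 1e-8 * max(np.max(np.abs(self.times)), 1.0):
            raise ValueError(
                "irregular time grid; discrete functional kernels require equal "
                "spacing -- use the continuous functional kernels"
            )
        return float(steps[0])

    def at_timepoint(self, index: int) -> AbundanceTable:
        """Cross-sectional table at one time point."""
        return AbundanceTable(
            values=self.values[:, :, index],
            sample_ids=list(self.individual_ids),
            taxon_ids=list(self.taxon_ids),
            scale="counts",
            provenance=list(self.provenance) + [f"time point t={self.times[index]:g}"],
        )

    def flattened(self) -> np.ndarray:
        """N x (D*T) matrix; taxon-major layout (taxon k occupies columns k*T..k*T+T-1)."""
        return self.values.reshape(self.n_individuals, self.n_taxa * self.n_timepoints)
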