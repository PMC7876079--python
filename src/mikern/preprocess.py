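"""Zero replacement, centered log-ratio transform and CSS normalization.

Sequencing abundance data is compositional: the library size is fixed by
the instrument, so only relative information is meaningful.  The clr
(centered log-ratio) transform maps each composition onto a zero-sum
real vector where Euclidean geometry is justified, but it requires
strictly positive entries — hence the pseudocount step.  Cumulative sum
scaling (CSS) is an alternative count normalization used here before the
non-compositional kernels.
"""

from __future__ import annotations

import numpy as np

from .tables import AbundanceTable, TimeSeriesTable

__all__ = ["replace_zeros", "clr_transform", "css_normalize", "clr_timeseries"]


def replace_zeros(table: AbundanceTable, pseudocount: float = 0.5) -> AbundanceTable:
    """Add a small pseudocount to *every* entry of the table.

    A value under the detection limit is added uniformly (not only to the
    zero cells), which keeps the perturbation identical across samples.
    The default of 0.5 corresponds to half of one read on the count scale.
    """
    if not np.isfinite(pseudocount) or pseudocount <= 0:
        raise ValueError(f"pseudocount must be a positive real, got {pseudocount}")
    out = table.values + pseudocount
    # A relative table stops summing to 1 after the shift; fall back to counts
    # scale semantics (clr is scale-invariant so this is immaterial downstream).
    return AbundanceTable(out, list(table.sample_ids), list(table.taxon_ids),
                          scale="counts",
                          provenance=list(table.provenance)
                          + [f"pseudocount {pseudocount:g} added to all entries"])


def _clr_matrix(values: np.ndarray) -> np.ndarray:
    logs = np.log(values)
    return logs - logs.mean(axis=1, keepdims=True)


def clr_transform(table: AbundanceTable) -> np.ndarray:
    """Centered log-ratio transform, row-wise: log(x_k / G(x)).

    G is the geometric mean of the row.  Every output row sums to zero and
    the transform is invariant to per-sample rescaling, which is what makes
    kernels built on it compositional.
    """
    if np.any(table.values <= 0):
        raise ValueError(
            "clr transform requires strictly positive entries; "
            "apply replace_zeros() first"
        )
    return _clr_matrix(table.values)


def css_normalize(table: AbundanceTable, quantile: float = 0.5) -> AbundanceTable:
    """Cumulative sum scaling of a count table.

    Each sample is divided by the sum of its counts that do not exceed the
    sample's ``quantile`` of nonzero counts, then rescaled by the median of
    those per-sample sums so magnitudes stay comparable across samples.
    Robust to a few very abundant taxa dominating the library size.
    """
    if not (0.0 < quantile < 1.0):
        raise ValueError(f"quantile must lie in (0, 1), got {quantile}")
    if table.scale != "counts":
        raise ValueError("CSS normalization applies to count tables")
    values = table.values
    n = values.shape[0]
    scale_sums = np.empty(n)
    for i in range(n):
        row = values[i]
        nonzero = row[row > 0]
        if nonzero.size == 0:
            raise ValueError(f"sample {table.sample_ids[i]!r} has all-zero counts")
        q = np.quantile(nonzero, quantile)
        scale_sums[i] = row[row <= q].sum()
        if scale_sums[i] == 0:  # pathological: every positive count above q
            scale_sums[i] = nonzero.min()
    common = float(np.median(scale_sums))
    out = values / scale_sums[:, None] * common
    return table.with_values(
        out, note=f"CSS normalized (quantile {quantile:g}, median scale {common:g})"
    )


def clr_timeseries(ts: TimeSeriesTable, pseudocount: float = 0.5) -> TimeSeriesTable:
    """Pseudocount + clr applied per (individual, time point) sample.

    Each cross-sectional composition is transformed independently, so the
    per-taxon time functions entering the functional kernels live on the
    clr scale.
    """
    if not np.isfinite(pseudocount) or pseudocount <= 0:
        raise ValueError(f"pseudocount must be a positive real, got {pseudocount}")
    if np.any(ts.values < 0):
        raise ValueError("clr preprocessing expects raw non-negative abundances")
    vals = ts.values + pseudocount
    logs = np.log(vals)
    clr = logs - logs.mean(axis=1, keepdims=True)  # center across taxa
    return TimeSeriesTable(
        values=clr,
        individual_ids=list(ts.individual_ids),
        taxon_ids=list(ts.taxon_ids),
        times=ts.times,
        observed=ts.observed,
        provenance=list(ts.provenance)
        + [f"pseudocount {pseudocount:g} + clr per (individual, time) sample"],
    )
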