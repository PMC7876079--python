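"""Functional kernels for longitudinal series.

Three time points per individual, class signal only at the last one.
Per-day models localize the signal; the discrete multivariate functional
RBF kernel (fRBF') classifies from the whole trajectory.
"""

import numpy as np
from scipy.spatial.distance import pdist, squareform

from mikern import (
    CVConfig,
    KernelMatrix,
    SimulationConfig,
    aitchison_sq_distances,
    clr_timeseries,
    median_heuristic_gamma,
    replace_zeros,
    replicate_evaluation,
    simulate_longitudinal,
)

res = simulate_longitudinal(SimulationConfig(
    n_individuals=150, n_taxa=100, n_informative=10, effect_size=2.0,
    n_timepoints=3, informative_timepoints=[3], seed=3))
cv = CVConfig(n_replicates=10, inner_repeats=2, seed=0)


def rbf_grid(d2, ids, name):
    grid = {}
    for f in (0.25, 1.0, 4.0):
        g = f * median_heuristic_gamma(d2)
        k = np.exp(-g * d2)
        np.fill_diagonal(k, 1.0)
        grid[g] = KernelMatrix(k, ids, {"name": name, "gamma": g})
    return grid


print("per-day Aitchison-RBF models (median test accuracy):")
for day in range(3):
    table = replace_zeros(res.timeseries.at_timepoint(day))
    rep = replicate_evaluation(
        rbf_grid(aitchison_sq_distances(table), table.sample_ids, "crbf"),
        res.y, cv, cost_grid=[0.1, 1.0, 10.0])
    print(f"  day {day + 1}: {rep.median:.3f}")

ts = clr_timeseries(res.timeseries)  # pseudocount + clr per (individual, day)
d2 = squareform(pdist(ts.flattened(), "sqeuclidean"))
rep = replicate_evaluation(rbf_grid(d2, ts.individual_ids, "frbf"), res.y, cv,
                           cost_grid=[0.1, 1.0, 10.0])
print(f"fRBF' on the full trajectories: {rep.median:.3f}")
print("days 1-2 sit at chance, day 3 and the longitudinal kernel are "
      "predictive — the signal is localized in time.")
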