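"""Delimited-text readers and writers for tables, kernels and reports.

All on-disk formats are TSV with header rows:

* abundance table — samples in rows, first column ``sample_id``,
  remaining columns taxa;
* kernel matrix — square, header row and first column both carrying
  sample ids; floats at 17 significant digits so write/read round-trips
  are bit-exact;
* long-format spatio-temporal table — columns ``sample_id``,
  ``individual_id``, ``time``, optional ``site``, then taxa; reshaped
  internally to :class:`~mikern.tables.TimeSeriesTable` objects.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .kernels import KernelMatrix
from .learn import EvalReport
from .tables import AbundanceTable, TimeSeriesTable

__all__ = [
    "read_abundance_table",
    "write_abundance_table",
    "read_metadata",
    "read_kernel_matrix",
    "write_kernel_matrix",
    "read_long_format",
    "write_long_format",
    "write_report",
]

_FLOAT_FMT = "%.17g"


def read_abundance_table(path, scale: str = "counts") -> AbundanceTable:
    """Read a samples x taxa TSV whose first column is ``sample_id``."""
    df = pd.read_csv(path, sep="\t", dtype={0: str}, float_precision="round_trip")
    if df.columns[0] != "sample_id":
        raise ValueError(
            f"{path}: first column must be 'sample_id', got {df.columns[0]!r}"
        )
    df = df.set_index("sample_id")
    if df.isna().any().any():
        bad = df.columns[df.isna().any()].tolist()
        raise ValueError(f"{path}: NaN values in columns {bad}")
    return AbundanceTable(df.to_numpy(dtype=float), list(df.index), list(df.columns),
                          scale=scale, provenance=[f"read from {Path(path).name}"])


def write_abundance_table(table: AbundanceTable, path) -> None:
    df = pd.DataFrame(table.values, index=pd.Index(table.sample_ids, name="sample_id"),
                      columns=table.taxon_ids)
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_metadata(path, sample_ids=None) -> pd.DataFrame:
    """Read a per-sample metadata TSV indexed by ``sample_id``.

    If ``sample_ids`` is given, validates eagerly that every sample has a
    metadata row, naming the missing ones.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str}, float_precision="round_trip")
    if df.columns[0] != "sample_id":
        raise ValueError(
            f"{path}: first column must be 'sample_id', got {df.columns[0]!r}"
        )
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"{path}: duplicate sample_ids {dups}")
    df = df.set_index("sample_id")
    if sample_ids is not None:
        missing = [s for s in sample_ids if s not in df.index]
        if missing:
            raise ValueError(f"{path}: metadata missing samples {missing}")
        df = df.loc[list(sample_ids)]
    return df


def write_kernel_matrix(K: KernelMatrix, path) -> None:
    df = pd.DataFrame(K.values, index=pd.Index(K.sample_ids, name="sample_id"),
                      columns=K.sample_ids)
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_kernel_matrix(path, meta: dict | None = None) -> KernelMatrix:
    """Read a square kernel TSV; symmetry is validated on construction."""
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if list(df.index.astype(str)) != [str(c) for c in df.columns]:
        raise ValueError(f"{path}: row and column sample_ids differ")
    return KernelMatrix(df.to_numpy(dtype=float), [str(s) for s in df.index],
                        meta or {"name": "precomputed", "source": str(path)})


def write_long_format(series_by_site, path) -> None:
    """Write one or several time-series tables as a single long-format TSV."""
    if isinstance(series_by_site, TimeSeriesTable):
        series_by_site = {None: series_by_site}
    rows = []
    for site, ts in series_by_site.items():
        for i, ind in enumerate(ts.individual_ids):
            for t, time in enumerate(ts.times):
                if ts.observed is not None and not ts.observed[i, t]:
                    continue
                row = {"sample_id": f"{ind}.t{t + 1}" + (f".{site}" if site else ""),
                       "individual_id": ind, "time": float(time)}
                if site is not None:
                    row["site"] = site
                row.update(dict(zip(ts.taxon_ids, ts.values[i, :, t])))
                rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def _pivot_timeseries(df: pd.DataFrame, taxa: list[str], label: str) -> TimeSeriesTable:
    times = np.array(sorted(df["time"].unique()), dtype=float)
    individuals = sorted(df["individual_id"].unique())
    n, d, t_n = len(individuals), len(taxa), times.size
    values = np.zeros((n, d, t_n))
    observed = np.zeros((n, t_n), dtype=bool)
    idx = {ind: i for i, ind in enumerate(individuals)}
    tdx = {t: j for j, t in enumerate(times)}
    for _, row in df.iterrows():
        i, j = idx[row["individual_id"]], tdx[float(row["time"])]
        if observed[i, j]:
            raise ValueError(
                f"duplicate (individual, time) sample: "
                f"({row['individual_id']!r}, {row['time']})"
            )
        observed[i, j] = True
        values[i, :, j] = row[taxa].to_numpy(dtype=float)
    return TimeSeriesTable(values, individuals, taxa, times,
                           observed=None if observed.all() else observed,
                           provenance=[label])


def read_long_format(path):
    """Read a long-format TSV into time-series tables.

    Returns a :class:`TimeSeriesTable` (no ``site`` column) or a dict
    mapping site name to one (with a ``site`` column).
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "individual_id": str},
                     float_precision="round_trip")
    required = {"sample_id", "individual_id", "time"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    meta_cols = ["sample_id", "individual_id", "time"]
    has_site = "site" in df.columns
    if has_site:
        meta_cols.append("site")
    taxa = [c for c in df.columns if c not in meta_cols]
    if not taxa:
        raise ValueError(f"{path}: no taxon columns found")
    if not has_site:
        return _pivot_timeseries(df, taxa, f"read from {Path(path).name}")
    return {
        site: _pivot_timeseries(sub, taxa, f"read from {Path(path).name}, site {site}")
        for site, sub in df.groupby("site")
    }


def write_report(report: EvalReport, path) -> None:
    """Serialize an evaluation report (per-replicate records) as JSON."""
    with open(path, "w") as fh:
        json.dump(report.as_dict(), fh, indent=2)
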