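"""Summaries of replicate time series: across-replicate bands, relative
change rescaling, and size-by-age distribution tables."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SummarySeries",
    "QUANTITIES",
    "relative_change",
    "size_age_distribution",
    "summarize_replicates",
    "plot_quantity",
]

#: Per-year quantities summarized across replicates.
QUANTITIES = (
    "mean_l_inf",
    "biomass_units",
    "n_fish",
    "mean_k",
    "mean_size_at_maturation",
    "mean_age_at_maturation",
)


@dataclass
class SummarySeries:
    """Across-replicate mean and empirical 95% band, one frame per quantity.

    Each frame has columns ``mean``, ``lo``, ``hi`` indexed by year.
    """

    tables: dict[str, pd.DataFrame]
    n_replicates: int
    n_extinct: int


def relative_change(series, baseline_years) -> np.ndarray:
    """Percent change of a per-year series relative to a baseline window.

    out(y) = 100 * (x(y) - mean(baseline)) / mean(baseline).  ``baseline_years``
    is an iterable of integer year indices into the series.
    """
    x = np.asarray(series, dtype=float)
    idx = np.asarray(list(baseline_years), dtype=int)
    if idx.size == 0 or idx.min() < 0 or idx.max() >= x.size:
        raise ValueError("baseline years must be a non-empty range within the series")
    base = x[idx].mean()
    if base == 0:
        raise ValueError("baseline mean is zero; relative change undefined")
    return 100.0 * (x - base) / base


def size_age_distribution(population, length_bins) -> pd.DataFrame:
    """Age x length-bin count table from a population snapshot.

    Rows are ages, columns the half-open bins ``(e_i, e_{i+1}]`` given by the
    edges, plus underflow/overflow columns so the counts always partition the
    population.
    """
    edges = np.asarray(length_bins, dtype=float)
    if edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("length_bins must be at least two strictly increasing edges")
    ages = np.asarray(population.age)
    lengths = np.asarray(population.length)
    labels = (
        [f"<={edges[0]:g}"]
        + [f"({a:g}, {b:g}]" for a, b in zip(edges[:-1], edges[1:])]
        + [f">{edges[-1]:g}"]
    )
    age_values = np.arange(0, int(ages.max()) + 1 if ages.size else 1)
    table = pd.DataFrame(0, index=age_values, columns=labels, dtype=int)
    if ages.size:
        col = np.searchsorted(edges, lengths, side="left")  # 0 = underflow
        for a in age_values:
            sel = ages == a
            if sel.any():
                counts = np.bincount(col[sel], minlength=len(labels))
                table.loc[a] = counts[: len(labels)]
    table.index.name = "age"
    return table


def summarize_replicates(runs, quantities=QUANTITIES) -> SummarySeries:
    """Across-replicate mean and 2.5/97.5 empirical percentile band per year.

    ``runs`` is a list of per-replicate annual-record DataFrames (or engine
    RunResults).  Extinct replicates already carry zeros after extinction;
    they are counted in ``n_extinct``.
    """
    frames, n_extinct = [], 0
    for r in runs:
        if hasattr(r, "records"):
            n_extinct += bool(getattr(r, "extinct", False))
            frames.append(r.records)
        else:
            frames.append(r)
    if not frames:
        raise ValueError("need at least one replicate")
    n_years = {len(f) for f in frames}
    if len(n_years) != 1:
        raise ValueError(f"replicates have mismatched lengths {sorted(n_years)}")
    tables = {}
    for q in quantities:
        stack = np.vstack([f[q].to_numpy(float) for f in frames])
        tables[q] = pd.DataFrame(
            {
                "mean": stack.mean(axis=0),
                "lo": np.percentile(stack, 2.5, axis=0),
                "hi": np.percentile(stack, 97.5, axis=0),
            }
        )
    return SummarySeries(tables=tables, n_replicates=len(frames), n_extinct=n_extinct)


def plot_quantity(summary: SummarySeries, quantity: str, ax=None, **kwargs):
    """Convenience line plot of one summarized quantity with its 95% band."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    t = summary.tables[quantity]
    years = t.index.to_numpy()
    ax.fill_between(years, t["lo"], t["hi"], alpha=0.3, linewidth=0)
    ax.plot(years, t["mean"], **kwargs)
    ax.set_xlabel("year")
    ax.set_ylabel(quantity)
    return ax
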