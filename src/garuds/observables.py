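"""Population observables: time series, phase portraits, percentile tables.

The order parameters tracked are the population means (and population
standard deviations) of the per-agent neighbor count ``n_i``, mean
alignment ``l_i`` and effective utility ``h_i`` at every step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import FlockState

__all__ = [
    "Snapshot",
    "TrajectoryRecord",
    "WindowStats",
    "phase_portrait",
    "equilibrium_window_stats",
    "utility_percentile_table",
    "utility_histogram",
    "DEFAULT_PERCENTILE_BANDS",
]

SUMMARY_COLUMNS = ["step", "n_mean", "n_std", "l_mean", "l_std", "h_mean", "h_std"]

#: Default rank bands (label, top fraction, bottom fraction) for the
#: percentile table.  Note the last two bands deliberately overlap: the
#: bottom half is reported both split (50-75%) and whole.
DEFAULT_PERCENTILE_BANDS = [
    ("Top 1%", 0.0, 0.01),
    ("Top 1-10%", 0.01, 0.10),
    ("Top 10-50%", 0.10, 0.50),
    ("Top 50-75%", 0.50, 0.75),
    ("Bottom 50%", 0.50, 1.0),
]


@dataclass(frozen=True)
class Snapshot:
    """Full per-agent state at one step, with derived quantities."""

    time_index: int
    state: FlockState
    neighbor_counts: np.ndarray
    mean_alignments: np.ndarray
    utilities: np.ndarray


@dataclass
class TrajectoryRecord:
    """Per-step population summaries plus optional full-state snapshots.

    ``summaries`` has one row per recorded step (``n_steps + 1`` rows
    including the initial state) with columns
    ``step, n_mean, n_std, l_mean, l_std, h_mean, h_std`` where the
    standard deviations are population (not sample) deviations across
    agents within the step.
    """

    summaries: pd.DataFrame
    snapshots: list[Snapshot] = field(default_factory=list)
    final_snapshot: Snapshot | None = None
    config: object | None = None
    params: object | None = None

    @property
    def n_steps(self) -> int:
        return len(self.summaries) - 1


@dataclass(frozen=True)
class WindowStats:
    """Mean +/- spread of the order parameters over a trailing window.

    Each spread pools the within-step population variance with the
    between-step variance of the per-step means, so it is comparable to a
    per-agent standard deviation taken over the whole window.
    """

    n_mean: float
    n_sd: float
    l_mean: float
    l_sd: float
    h_mean: float
    h_sd: float


def phase_portrait(record: TrajectoryRecord) -> np.ndarray:
    """Ordered trajectory of population means in the (n, l) plane."""
    if len(record.summaries) == 0:
        raise ValueError("record is empty")
    return record.summaries[["n_mean", "l_mean"]].to_numpy()


def _pooled(means: np.ndarray, stds: np.ndarray) -> tuple[float, float]:
    m = float(np.mean(means))
    sd = float(np.sqrt(np.mean(stds**2) + np.var(means)))
    return m, sd


def equilibrium_window_stats(record: TrajectoryRecord, window: int = 100) -> WindowStats:
    """Order-parameter statistics over the final ``window`` recorded steps."""
    if not (0 < window <= len(record.summaries)):
        raise ValueError(f"window must be in [1, {len(record.summaries)}], got {window}")
    tail = record.summaries.iloc[-window:]
    n_mean, n_sd = _pooled(tail["n_mean"].to_numpy(), tail["n_std"].to_numpy())
    l_mean, l_sd = _pooled(tail["l_mean"].to_numpy(), tail["l_std"].to_numpy())
    h_mean, h_sd = _pooled(tail["h_mean"].to_numpy(), tail["h_std"].to_numpy())
    return WindowStats(n_mean, n_sd, l_mean, l_sd, h_mean, h_sd)


def utility_percentile_table(
    utilities: np.ndarray,
    bands: list[tuple[str, float, float]] | None = None,
) -> pd.DataFrame:
    """Mean utility within rank bands of the population.

    Agents are ranked descending by utility (ties broken by agent index);
    the band ``(label, a, b)`` covers ranks ``[floor(N*a), floor(N*b))``.
    """
    u = np.asarray(utilities, dtype=np.float64)
    if u.size == 0:
        raise ValueError("utilities must be nonempty")
    if bands is None:
        bands = DEFAULT_PERCENTILE_BANDS
    order = np.lexsort((np.arange(u.size), -u))
    ranked = u[order]
    rows = []
    for label, lo, hi in bands:
        i0, i1 = int(np.floor(u.size * lo)), int(np.floor(u.size * hi))
        if i1 <= i0:
            raise ValueError(f"band {label!r} is empty for N={u.size}")
        rows.append({"band": label, "size": i1 - i0, "mean_utility": float(np.mean(ranked[i0:i1]))})
    return pd.DataFrame(rows)


def utility_histogram(utilities: np.ndarray, bin_width: float) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of per-agent utilities on a grid aligned to ``bin_width``.

    Returns ``(counts, edges)``; counts sum to N.  An empty input yields
    empty arrays.
    """
    if not (bin_width > 0):
        raise ValueError("bin_width must be positive")
    u = np.asarray(utilities, dtype=np.float64)
    if u.size == 0:
        return np.array([], dtype=np.int64), np.array([], dtype=np.float64)
    start = np.floor(u.min() / bin_width) * bin_width
    n_bins = int(np.floor((u.max() - start) / bin_width)) + 1
    edges = start + bin_width * np.arange(n_bins + 1)
    counts, edges = np.histogram(u, bins=edges)
    return counts, edges


def plot_phase_portrait(record: TrajectoryRecord, ax=None):
    """Minimal phase-portrait plot (requires matplotlib; not a contract)."""
    import matplotlib.pyplot as plt

    pts = phase_portrait(record)
    if ax is None:
        _, ax = plt.subplots()
    ax.plot(pts[:, 0], pts[:, 1], "-", lw=0.8, alpha=0.7)
    ax.scatter(pts[[0, -1], 0], pts[[0, -1], 1], c=["tab:red", "tab:green"], zorder=3)
    ax.set_xlabel("mean neighbors $\\bar{n}$")
    ax.set_ylabel("mean alignment $\\bar{l}$")
    return ax
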