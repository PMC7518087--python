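"""Measured quantities: growth records, doubling-time statistics and
histograms, quiescence onset, exponential growth-rate fits, and snapshot
rendering.

Doubling-time statistics use the *population* standard deviation (divide by
N).  Undefined results on an empty or degenerate population are reported as
``nan`` markers rather than exceptions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .state import LatticeState, QUIESCENT

__all__ = [
    "GrowthRecord",
    "Snapshot",
    "SimulationResult",
    "doubling_time_stats",
    "quiescence_onset",
    "fit_growth_rate",
    "fit_rate_after_crossing",
    "histogram_doubling_times",
    "skewness_doubling_times",
    "render_snapshot",
    "write_growth_csv",
    "read_growth_csv",
    "write_histogram_csv",
    "GROWTH_CSV_COLUMNS",
]

GROWTH_CSV_COLUMNS = [
    "t_h",
    "n_total",
    "n_prolif",
    "n_quiesc",
    "cum_mitotic_deaths",
    "cum_random_deaths",
    "mean_tau_h",
    "sd_tau_h",
]

#: Default doubling-time histogram bin edges (h), covering both pools.
DEFAULT_TAU_EDGES = np.arange(8.0, 44.0 + 1e-9, 1.0)


@dataclass(frozen=True)
class GrowthRecord:
    """One time point of the growth curve."""

    t: float
    n_total: int
    n_proliferating: int
    n_quiescent: int
    cum_mitotic_deaths: int
    cum_random_deaths: int
    mean_tau: float
    sd_tau: float

    @classmethod
    def from_state(cls, state: LatticeState) -> "GrowthRecord":
        mean_tau, sd_tau = doubling_time_stats(state)
        return cls(
            t=state.t,
            n_total=state.n_cells,
            n_proliferating=state.n_proliferating,
            n_quiescent=state.n_quiescent,
            cum_mitotic_deaths=state.mitotic_deaths,
            cum_random_deaths=state.random_deaths,
            mean_tau=mean_tau,
            sd_tau=sd_tau,
        )


@dataclass(frozen=True)
class Snapshot:
    """Spatial state at one time.

    ``state_grid`` codes: 0 empty, 1 proliferating, 2 quiescent.
    ``tau_grid`` holds the doubling time per occupied site (nan elsewhere).
    ``died_positions`` are sites of cells that died since the previous
    snapshot (rendering overlay only: lysis frees the site instantly).
    """

    t: float
    state_grid: np.ndarray
    tau_grid: np.ndarray
    died_positions: np.ndarray


@dataclass
class SimulationResult:
    """Full output of one simulation run."""

    records: list[GrowthRecord]
    snapshots: list[Snapshot]
    initial_doubling_times: np.ndarray
    final_doubling_times: np.ndarray
    stop_reason: str  # "t_max" | "edge" | "extinct" | "quiescent_stop"
    seed: int
    config: dict = field(default_factory=dict)

    def records_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_h": [r.t for r in self.records],
                "n_total": [r.n_total for r in self.records],
                "n_prolif": [r.n_proliferating for r in self.records],
                "n_quiesc": [r.n_quiescent for r in self.records],
                "cum_mitotic_deaths": [r.cum_mitotic_deaths for r in self.records],
                "cum_random_deaths": [r.cum_random_deaths for r in self.records],
                "mean_tau_h": [r.mean_tau for r in self.records],
                "sd_tau_h": [r.sd_tau for r in self.records],
            }
        )

    def histogram(self, which: str = "final", bin_edges: np.ndarray | None = None):
        """(edges, counts) histogram of the initial or final doubling times."""
        edges = DEFAULT_TAU_EDGES if bin_edges is None else np.asarray(bin_edges, float)
        values = (
            self.initial_doubling_times if which == "initial" else self.final_doubling_times
        )
        counts, _ = np.histogram(values, bins=edges)
        return edges, counts


# -- scalar observables -----------------------------------------------------


def _alive_tau(obj) -> np.ndarray:
    if isinstance(obj, LatticeState):
        return obj.tau
    return np.asarray(obj, dtype=float)


def doubling_time_stats(state) -> tuple[float, float]:
    """Population mean and population sd of the alive cells' doubling times.

    Returns ``(nan, nan)`` for an empty population.
    """
    tau = _alive_tau(state)
    if tau.size == 0:
        return (math.nan, math.nan)
    return float(tau.mean()), float(tau.std(ddof=0))


def quiescence_onset(
    records: Sequence[GrowthRecord], fraction_threshold: float = 0.01
) -> float | None:
    """Earliest recorded time at which the quiescent fraction reaches the
    threshold; ``None`` if it never does."""
    if not records:
        raise ValueError("records must be non-empty")
    if not 0.0 < fraction_threshold < 1.0:
        raise ValueError("fraction_threshold must lie in (0, 1)")
    for r in records:
        if r.n_total > 0 and r.n_quiescent / r.n_total >= fraction_threshold:
            return r.t
    return None


def fit_growth_rate(
    records: Sequence[GrowthRecord], t_window: tuple[float, float]
) -> float:
    """Exponential growth rate (per hour): least-squares slope of
    ``ln n_total`` vs ``t`` over the records falling in ``t_window``."""
    t0, t1 = t_window
    pts = [r for r in records if t0 <= r.t <= t1]
    if len(pts) < 3:
        raise ValueError("need at least 3 records in the window")
    n = np.array([r.n_total for r in pts], dtype=float)
    if np.any(n == 0):
        raise ValueError("population extinct inside the fit window")
    t = np.array([r.t for r in pts])
    slope, _ = np.polyfit(t, np.log(n), 1)
    return float(slope)


def fit_rate_after_crossing(
    records: Sequence[GrowthRecord], n_ref: int, duration: float
) -> float | None:
    """Growth rate fitted over a fixed-length window anchored at the first
    time the population reaches ``n_ref`` cells.

    Anchoring at a common population size makes regrowth rates of runs that
    restart from different depths comparable.  Returns ``None`` if the
    population never reaches ``n_ref`` or the window is not fully recorded.
    """
    t_cross = None
    for r in records:
        if r.n_total >= n_ref:
            t_cross = r.t
            break
    if t_cross is None:
        return None
    t_end = t_cross + duration
    if not records or records[-1].t < t_end:
        return None
    return fit_growth_rate(records, (t_cross, t_end))


def histogram_doubling_times(state, bin_edges: np.ndarray) -> np.ndarray:
    """Counts of alive-cell doubling times per bin (edges strictly increasing)."""
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    tau = _alive_tau(state)
    counts, _ = np.histogram(tau, bins=edges)
    return counts


def skewness_doubling_times(state) -> float:
    """Standardized third central moment of the alive doubling times.

    ``nan`` when fewer than 3 cells or when the spread is zero.
    """
    tau = _alive_tau(state)
    if tau.size < 3:
        return math.nan
    sd = tau.std(ddof=0)
    if sd == 0:
        return math.nan
    return float(((tau - tau.mean()) ** 3).mean() / sd**3)


# -- snapshot rendering ------------------------------------------------------

#: Display codes used in rendered state grids.
SNAPSHOT_EMPTY, SNAPSHOT_PROLIF, SNAPSHOT_QUIESCENT, SNAPSHOT_DIED = 0, 1, 2, 3


def snapshot_from_state(state: LatticeState, died_positions=None) -> Snapshot:
    """Capture the spatial configuration of ``state``."""
    L = state.geometry.side_sites
    sgrid = np.zeros((L, L), dtype=np.uint8)
    sgrid[state.rows, state.cols] = np.where(
        state.state == QUIESCENT, SNAPSHOT_QUIESCENT, SNAPSHOT_PROLIF
    )
    tgrid = np.full((L, L), np.nan)
    tgrid[state.rows, state.cols] = state.tau
    died = (
        np.empty((0, 2), dtype=np.int64)
        if died_positions is None
        else np.asarray(died_positions, dtype=np.int64).reshape(-1, 2)
    )
    return Snapshot(t=state.t, state_grid=sgrid, tau_grid=tgrid, died_positions=died)


def render_snapshot(
    snapshot: Snapshot,
    mode: str = "state",
    out_png: str | None = None,
    out_table: str | None = None,
):
    """Render a snapshot (blue = proliferating, green = quiescent, red = died
    since the previous snapshot; phenotype mode maps tau onto a colormap).

    Returns the numeric display grid; optionally writes a PNG and a
    plain-text grid table.
    """
    if mode not in ("state", "phenotype"):
        raise ValueError("mode must be 'state' or 'phenotype'")
    if mode == "state":
        display = snapshot.state_grid.astype(np.int16).copy()
        for r, c in snapshot.died_positions:
            if display[r, c] == SNAPSHOT_EMPTY:
                display[r, c] = SNAPSHOT_DIED
    else:
        display = snapshot.tau_grid

    if out_png is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        from matplotlib.colors import ListedColormap

        fig, ax = plt.subplots(figsize=(6, 6))
        if mode == "state":
            cmap = ListedColormap(["white", "tab:blue", "tab:green", "tab:red"])
            ax.imshow(display, cmap=cmap, vmin=0, vmax=3, interpolation="nearest")
        else:
            im = ax.imshow(display, cmap="viridis", interpolation="nearest")
            fig.colorbar(im, ax=ax, label="doubling time (h)")
        ax.set_title(f"t = {snapshot.t:g} h")
        ax.set_xticks([])
        ax.set_yticks([])
        fig.savefig(out_png, dpi=150)
        plt.close(fig)

    if out_table is not None:
        fmt = "%d" if mode == "state" else "%.3f"
        np.savetxt(out_table, display, fmt=fmt, delimiter="\t")
    return display


# -- file IO -----------------------------------------------------------------


def write_growth_csv(result_or_records, path) -> None:
    """Write the growth curve as CSV with the standard header."""
    if isinstance(result_or_records, SimulationResult):
        df = result_or_records.records_dataframe()
    else:
        df = SimulationResult(
            records=list(result_or_records),
            snapshots=[],
            initial_doubling_times=np.empty(0),
            final_doubling_times=np.empty(0),
            stop_reason="t_max",
            seed=0,
        ).records_dataframe()
    df.to_csv(path, index=False)


def read_growth_csv(path) -> list[GrowthRecord]:
    df = pd.read_csv(path)
    return [
        GrowthRecord(
            t=row.t_h,
            n_total=int(row.n_total),
            n_proliferating=int(row.n_prolif),
            n_quiescent=int(row.n_quiesc),
            cum_mitotic_deaths=int(row.cum_mitotic_deaths),
            cum_random_deaths=int(row.cum_random_deaths),
            mean_tau=row.mean_tau_h,
            sd_tau=row.sd_tau_h,
        )
        for row in df.itertuples()
    ]


def write_histogram_csv(edges: np.ndarray, counts: np.ndarray, path) -> None:
    pd.DataFrame(
        {"bin_lo": edges[:-1], "bin_hi": edges[1:], "count": counts}
    ).to_csv(path, index=False)
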