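"""Lattice geometry and the cell-population state container.

Cells live on a square 2-D lattice; each 20 x 20 um site holds at most one
cell.  For performance the population is stored as flat numpy arrays (one
entry per alive cell) plus an integer occupancy grid mapping each site to
the index of the cell on it (-1 = empty).  :class:`Cell` is a light
per-cell view used in tests and small-scale manipulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Geometry", "Cell", "LatticeState", "PROLIFERATING", "QUIESCENT"]

PROLIFERATING = 0
QUIESCENT = 1

_STATE_NAMES = {PROLIFERATING: "proliferating", QUIESCENT: "quiescent"}


@dataclass(frozen=True)
class Geometry:
    """Square lattice geometry.

    Parameters
    ----------
    side_sites : int
        Grid side L in sites.
    site_um : float
        Side of one lattice site in micrometers (default 20).
    """

    side_sites: int
    site_um: float = 20.0

    def __post_init__(self) -> None:
        if self.side_sites < 1:
            raise ValueError("side_sites must be >= 1")
        if self.site_um <= 0:
            raise ValueError("site_um must be positive")

    @property
    def center(self) -> tuple[int, int]:
        """The site used as the seeding-circle center."""
        c = self.side_sites // 2
        return (c, c)

    def check_fits_circle(self, radius_um: float, margin_fraction: float = 0.1) -> None:
        """Raise if the seed circle plus the edge-stop margin does not fit."""
        r_sites = radius_um / self.site_um
        if r_sites + margin_fraction * self.side_sites > self.side_sites / 2:
            raise ValueError(
                f"seed circle radius {radius_um} um plus {margin_fraction:.0%} margin "
                f"does not fit in a {self.side_sites}-site grid"
            )


@dataclass(frozen=True)
class Cell:
    """Read-only view of one cell."""

    pos: tuple[int, int]
    tau: float
    age: float
    state: str  # "proliferating" | "quiescent"


class LatticeState:
    """Population state: per-cell arrays, the occupancy grid, the clock, and
    cumulative event counters.

    Invariants (checked by :meth:`validate`): one cell per site, the
    occupancy grid and the cell arrays agree bijectively, and
    ``n_cells == n0 + births - mitotic_deaths - random_deaths``.
    """

    def __init__(
        self,
        geometry: Geometry,
        rows: np.ndarray,
        cols: np.ndarray,
        tau: np.ndarray,
        age: np.ndarray,
        state: np.ndarray | None = None,
        t: float = 0.0,
    ) -> None:
        n = len(rows)
        self.geometry = geometry
        self.rows = np.asarray(rows, dtype=np.int64).copy()
        self.cols = np.asarray(cols, dtype=np.int64).copy()
        self.tau = np.asarray(tau, dtype=np.float64).copy()
        self.age = np.asarray(age, dtype=np.float64).copy()
        if state is None:
            self.state = np.zeros(n, dtype=np.uint8)
        else:
            self.state = np.asarray(state, dtype=np.uint8).copy()
        if not (len(self.cols) == len(self.tau) == len(self.age) == len(self.state) == n):
            raise ValueError("cell arrays must have equal length")
        if np.any(self.tau <= 0):
            raise ValueError("all doubling times must be positive")
        if np.any(self.age < 0):
            raise ValueError("ages must be non-negative")
        L = geometry.side_sites
        if n and (
            self.rows.min() < 0 or self.rows.max() >= L
            or self.cols.min() < 0 or self.cols.max() >= L
        ):
            raise ValueError("cell positions outside the grid")
        self.t = float(t)
        self.n0 = n
        self.births = 0
        self.mitotic_deaths = 0
        self.random_deaths = 0
        self.grid = np.full((L, L), -1, dtype=np.int64)
        self.grid[self.rows, self.cols] = np.arange(n)
        if n and int((self.grid >= 0).sum()) != n:
            raise ValueError("two cells share a lattice site")

    # -- basic queries ------------------------------------------------------

    @property
    def n_cells(self) -> int:
        return len(self.rows)

    @property
    def n_quiescent(self) -> int:
        return int((self.state == QUIESCENT).sum())

    @property
    def n_proliferating(self) -> int:
        return self.n_cells - self.n_quiescent

    def cells(self):
        """Iterate over :class:`Cell` views (test/inspection convenience)."""
        for i in range(self.n_cells):
            yield self.cell_at_index(i)

    def cell_at_index(self, i: int) -> Cell:
        return Cell(
            pos=(int(self.rows[i]), int(self.cols[i])),
            tau=float(self.tau[i]),
            age=float(self.age[i]),
            state=_STATE_NAMES[int(self.state[i])],
        )

    def index_at(self, pos: tuple[int, int]) -> int:
        """Cell-array index at a site, or -1 if the site is empty."""
        return int(self.grid[pos[0], pos[1]])

    # -- mutation helpers used by the engine --------------------------------

    def remove_cells(self, mask: np.ndarray) -> None:
        """Remove the cells flagged in the boolean ``mask`` and re-index the grid."""
        if not mask.any():
            return
        self.grid[self.rows[mask], self.cols[mask]] = -1
        keep = ~mask
        self.rows = self.rows[keep]
        self.cols = self.cols[keep]
        self.tau = self.tau[keep]
        self.age = self.age[keep]
        self.state = self.state[keep]
        self.grid[self.rows, self.cols] = np.arange(len(self.rows))

    def append_cells(
        self, rows: np.ndarray, cols: np.ndarray, tau: np.ndarray,
        age: np.ndarray | None = None, state: np.ndarray | None = None,
        update_grid: bool = True,
    ) -> None:
        """Append daughter cells (proliferating, age 0 unless given)."""
        k = len(rows)
        if k == 0:
            return
        n = self.n_cells
        self.rows = np.concatenate([self.rows, np.asarray(rows, dtype=np.int64)])
        self.cols = np.concatenate([self.cols, np.asarray(cols, dtype=np.int64)])
        self.tau = np.concatenate([self.tau, np.asarray(tau, dtype=np.float64)])
        self.age = np.concatenate(
            [self.age, np.zeros(k) if age is None else np.asarray(age, dtype=np.float64)]
        )
        self.state = np.concatenate(
            [self.state, np.zeros(k, dtype=np.uint8) if state is None
             else np.asarray(state, dtype=np.uint8)]
        )
        if update_grid:
            self.grid[self.rows[n:], self.cols[n:]] = np.arange(n, n + k)

    # -- consistency --------------------------------------------------------

    def validate(self) -> None:
        """Check the occupancy bijection and the conservation identity."""
        occ = np.argwhere(self.grid >= 0)
        if len(occ) != self.n_cells:
            raise AssertionError("occupied-site count != cell count")
        idx = self.grid[self.rows, self.cols]
        if not np.array_equal(idx, np.arange(self.n_cells)):
            raise AssertionError("grid indices are not a bijection onto cells")
        if self.n_cells != self.n0 + self.births - self.mitotic_deaths - self.random_deaths:
            raise AssertionError("conservation identity violated")
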