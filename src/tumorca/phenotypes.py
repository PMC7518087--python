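"""Doubling-time phenotype pools.

Intrinsic proliferative heterogeneity is modelled as a finite pool of
cell-cycle durations (doubling times, hours).  A pool is drawn once per
simulation from a normal or uniform distribution with a given mean and
standard deviation, or is degenerate (homogeneous).  Each seeded cell is
then assigned one pool value, which its descendants inherit exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DoublingTimePool",
    "uniform_bounds",
    "draw_phenotype_pool",
    "assign_phenotypes",
]

#: Minimum admissible doubling time (h); normal draws at or below this are redrawn.
MIN_DOUBLING_TIME_H = 1.0

POOL_KINDS = ("normal", "uniform", "homogeneous")


@dataclass(frozen=True)
class DoublingTimePool:
    """A finite set of doubling times (h) from which cells inherit their cycle length.

    Attributes
    ----------
    values : numpy array of float
        The pool of doubling times, all strictly positive.
    kind : {"normal", "uniform", "homogeneous"}
        Parent distribution the pool was drawn from.
    mean : float
        Target mean of the parent distribution (h).
    sd : float
        Target standard deviation of the parent distribution (h).
    """

    values: np.ndarray
    kind: str
    mean: float
    sd: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("pool must be a non-empty 1-D array")
        if np.any(self.values <= 0):
            raise ValueError("all doubling times must be positive")

    @property
    def pool_size(self) -> int:
        return int(self.values.size)


def uniform_bounds(mean: float, sd: float) -> tuple[float, float]:
    """Bounds (a, b) of the unique uniform distribution with the given mean and sd.

    A uniform on (a, b) has mean (a+b)/2 and standard deviation (b-a)/sqrt(12),
    so a = mean - sd*sqrt(3) and b = mean + sd*sqrt(3).

    Raises
    ------
    ValueError
        If the implied lower bound would be non-positive (sd*sqrt(3) >= mean).
    """
    if mean <= 0:
        raise ValueError("mean must be positive")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    half_width = sd * math.sqrt(3.0)
    if half_width >= mean:
        raise ValueError(
            f"sd={sd} too large for mean={mean}: lower uniform bound would be non-positive"
        )
    return mean - half_width, mean + half_width


def draw_phenotype_pool(
    kind: str,
    pool_size: int,
    mean: float,
    sd: float,
    rng: np.random.Generator,
) -> DoublingTimePool:
    """Draw a pool of ``pool_size`` doubling times from the named distribution.

    ``kind='homogeneous'`` ignores ``sd`` and returns ``pool_size`` copies of
    ``mean``.  Normal draws at or below :data:`MIN_DOUBLING_TIME_H` are redrawn
    (truncation guard; essentially never triggered at the default mean 24 h,
    sd 4.8 h).  Deterministic for a given ``rng`` state.
    """
    if pool_size < 1:
        raise ValueError("pool_size must be >= 1")
    if mean <= 0:
        raise ValueError("mean must be positive")
    if kind == "homogeneous":
        values = np.full(pool_size, float(mean))
    elif kind == "uniform":
        lo, hi = uniform_bounds(mean, sd)
        values = rng.uniform(lo, hi, size=pool_size)
    elif kind == "normal":
        values = rng.normal(mean, sd, size=pool_size)
        bad = values <= MIN_DOUBLING_TIME_H
        while np.any(bad):
            values[bad] = rng.normal(mean, sd, size=int(bad.sum()))
            bad = values <= MIN_DOUBLING_TIME_H
    else:
        raise ValueError(f"unknown pool kind {kind!r}; expected one of {POOL_KINDS}")
    return DoublingTimePool(values=values, kind=kind, mean=float(mean), sd=float(sd))


def assign_phenotypes(
    pool: DoublingTimePool, n_cells: int, rng: np.random.Generator
) -> np.ndarray:
    """Assign each of ``n_cells`` cells a doubling time drawn uniformly,
    with replacement, from the pool."""
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if pool.pool_size == 0:
        raise ValueError("empty pool")
    idx = rng.integers(0, pool.pool_size, size=n_cells)
    return pool.values[idx]
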