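"""Initial spatial configurations.

Two seeding modes are used throughout: a *sparse* one (5,000 cells scattered
at ~1% density in an 8 mm-radius circle, mimicking a 2-D in-vitro culture)
and a *dense* one (1,000 cells packed at ~80% in a 0.4 mm-radius circle,
mimicking a central plane of a solid tumor).  Placement is uniform random
among in-circle sites without replacement; circle membership is decided by
the Euclidean distance between site centers (<= radius), with the circle
center on the central site of the grid.
"""

from __future__ import annotations

import numpy as np

from .state import Geometry, LatticeState

__all__ = [
    "sites_in_circle",
    "circle_sites",
    "seed_circle",
    "seed_sparse",
    "seed_dense",
    "assign_initial_ages",
    "SPARSE_RADIUS_UM",
    "DENSE_RADIUS_UM",
]

SPARSE_RADIUS_UM = 8000.0
DENSE_RADIUS_UM = 400.0


def circle_sites(
    geometry: Geometry, radius_um: float, center: tuple[int, int] | None = None
) -> np.ndarray:
    """(n, 2) array of (row, col) sites whose centers lie within ``radius_um``
    of the center site's center, clipped to the grid, in row-major order."""
    if radius_um < 0:
        raise ValueError("radius must be non-negative")
    L = geometry.side_sites
    cr, cc = center if center is not None else geometry.center
    r_sites = radius_um / geometry.site_um
    k = int(np.floor(r_sites))
    r0, r1 = max(0, cr - k), min(L - 1, cr + k)
    c0, c1 = max(0, cc - k), min(L - 1, cc + k)
    rr, cc2 = np.meshgrid(np.arange(r0, r1 + 1), np.arange(c0, c1 + 1), indexing="ij")
    inside = (rr - cr) ** 2 + (cc2 - cc) ** 2 <= r_sites**2
    return np.column_stack([rr[inside], cc2[inside]])


def sites_in_circle(radius_um: float, site_size_um: float = 20.0) -> int:
    """Number of lattice sites whose centers fall within ``radius_um`` of a
    site center (the center site itself counts: distance 0)."""
    if radius_um < 0:
        raise ValueError("radius must be non-negative")
    if site_size_um <= 0:
        raise ValueError("site size must be positive")
    k = int(np.floor(radius_um / site_size_um))
    side = 2 * k + 1
    geom = Geometry(side_sites=max(side, 1), site_um=site_size_um)
    return len(circle_sites(geom, radius_um, center=(k, k)))


def seed_circle(
    geometry: Geometry,
    radius_um: float,
    n_cells: int,
    phenotypes: np.ndarray,
    ages: np.ndarray,
    rng: np.random.Generator,
) -> LatticeState:
    """Place ``n_cells`` cells on distinct uniformly-random in-circle sites.

    All cells start proliferating.  ``phenotypes`` and ``ages`` must have
    length ``n_cells``.
    """
    if n_cells < 0:
        raise ValueError("n_cells must be non-negative")
    if len(phenotypes) != n_cells or len(ages) != n_cells:
        raise ValueError("phenotypes and ages must have length n_cells")
    geometry.check_fits_circle(radius_um)
    sites = circle_sites(geometry, radius_um)
    if n_cells > len(sites):
        raise ValueError(
            f"cannot place {n_cells} cells on {len(sites)} in-circle sites"
        )
    chosen = rng.choice(len(sites), size=n_cells, replace=False)
    picked = sites[chosen]
    return LatticeState(
        geometry,
        rows=picked[:, 0],
        cols=picked[:, 1],
        tau=np.asarray(phenotypes, dtype=float),
        age=np.asarray(ages, dtype=float),
    )


def seed_sparse(
    geometry: Geometry,
    n_cells: int,
    phenotypes: np.ndarray,
    ages: np.ndarray,
    rng: np.random.Generator,
    radius_um: float = SPARSE_RADIUS_UM,
) -> LatticeState:
    """Sparse in-vitro-like seeding (default: 8 mm-radius circle)."""
    return seed_circle(geometry, radius_um, n_cells, phenotypes, ages, rng)


def seed_dense(
    geometry: Geometry,
    n_cells: int,
    phenotypes: np.ndarray,
    ages: np.ndarray,
    rng: np.random.Generator,
    radius_um: float = DENSE_RADIUS_UM,
) -> LatticeState:
    """Dense tumor-plane-like seeding (default: 0.4 mm-radius circle)."""
    return seed_circle(geometry, radius_um, n_cells, phenotypes, ages, rng)


def assign_initial_ages(
    doubling_times: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Random initial cell-cycle ages: age_i ~ Uniform[0, tau_i)."""
    tau = np.asarray(doubling_times, dtype=float)
    if np.any(tau <= 0):
        raise ValueError("all doubling times must be positive")
    return rng.uniform(0.0, tau)
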