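"""The cellular-automaton update loop.

Each cell carries an inherited doubling time tau and an age (time spent in
the cycle).  Per time step of length ``dt``:

1. if a random (cell-cycle-non-specific) death model is active, every alive
   cell — proliferating or quiescent — dies with probability
   ``1 - exp(-lambda*dt)``;
2. surviving cells age by ``dt`` plus a small zero-mean uniform noise term
   (a desynchronizer, clamped so age never goes negative); cells whose age
   has reached tau are then visited in a fresh random order: a cell with no
   free site in its 2-Moore neighborhood becomes quiescent (age retained),
   otherwise, if mitotic treatment is active, it dies with probability
   ``p_m`` at the moment of mitosis; otherwise it divides onto a uniformly
   chosen free neighbor site, both daughters resetting their age to 0;
3. the clock advances.

Quiescence is re-evaluated every step: a quiescent cell whose neighborhood
frees up divides like any other ripe cell.  Dead cells are removed
instantly (rapid lysis), freeing their site within the same step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .config import RunConfig
from .observables import (
    GrowthRecord,
    SimulationResult,
    Snapshot,
    snapshot_from_state,
)
from .phenotypes import assign_phenotypes, draw_phenotype_pool
from .seeding import assign_initial_ages, seed_circle
from .state import PROLIFERATING, QUIESCENT, Cell, Geometry, LatticeState
from .treatment import (
    NO_TREATMENT,
    TreatmentSchedule,
    mitotic_death_roll,
    random_death_prob,
    schedule_active,
)

__all__ = [
    "SimConfig",
    "StepTallies",
    "free_neighbors_moore2",
    "advance_age",
    "attempt_division",
    "step",
    "edge_reached",
    "run_simulation",
]

logger = logging.getLogger("tumorca")


@dataclass(frozen=True)
class SimConfig:
    """Step-level engine settings (see :class:`tumorca.config.EngineConfig`
    for the user-facing run configuration)."""

    dt: float = 1.0
    t_max: float = 1200.0
    age_noise_amp: float = 0.1
    edge_margin_fraction: float = 0.1


@dataclass(frozen=True)
class StepTallies:
    """Events of one step."""

    births: int = 0
    mitotic_deaths: int = 0
    random_deaths: int = 0
    became_quiescent: int = 0
    died_positions: np.ndarray | None = None  # (k, 2) sites freed by death


# -- per-cell operations (reference / small-scale API) -----------------------


def free_neighbors_moore2(state: LatticeState, pos: tuple[int, int]) -> list[tuple[int, int]]:
    """Empty sites within Chebyshev distance 2 of ``pos`` (up to 24),
    clipped at the grid boundary, in row-major order."""
    L = state.geometry.side_sites
    r, c = pos
    if not (0 <= r < L and 0 <= c < L):
        raise ValueError("pos outside grid")
    out = []
    for dr in range(-2, 3):
        rr = r + dr
        if rr < 0 or rr >= L:
            continue
        for dc in range(-2, 3):
            if dr == 0 and dc == 0:
                continue
            cc = c + dc
            if cc < 0 or cc >= L:
                continue
            if state.grid[rr, cc] == -1:
                out.append((rr, cc))
    return out


def advance_age(cell: Cell, dt: float, noise_amp: float, rng: np.random.Generator) -> Cell:
    """Age a cell by ``dt`` plus Uniform(-noise_amp, +noise_amp) noise,
    clamped at zero."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    eps = rng.uniform(-noise_amp, noise_amp) if noise_amp > 0 else 0.0
    return Cell(pos=cell.pos, tau=cell.tau, age=max(0.0, cell.age + dt + eps), state=cell.state)


def attempt_division(
    state: LatticeState, index: int, mitotic_p: float, rng: np.random.Generator
) -> str:
    """Resolve one ripe cell: returns ``"divided"``, ``"quiescent"`` or
    ``"mitotic_death"``.  ``mitotic_p`` is the active mitotic death
    probability (0 when no mitotic treatment applies)."""
    if state.age[index] < state.tau[index]:
        raise ValueError("attempt_division called on a cell with age < tau")
    pos = (int(state.rows[index]), int(state.cols[index]))
    free = free_neighbors_moore2(state, pos)
    if not free:
        state.state[index] = QUIESCENT
        return "quiescent"
    if mitotic_p > 0 and mitotic_death_roll(mitotic_p, rng):
        mask = np.zeros(state.n_cells, dtype=bool)
        mask[index] = True
        state.remove_cells(mask)
        state.mitotic_deaths += 1
        return "mitotic_death"
    site = free[int(rng.integers(len(free)))]
    state.age[index] = 0.0
    state.state[index] = PROLIFERATING
    state.append_cells(
        rows=np.array([site[0]]), cols=np.array([site[1]]),
        tau=np.array([state.tau[index]]),
    )
    state.births += 1
    return "divided"


# -- the step ----------------------------------------------------------------


def _ripe_sweep_py(grid, rows, cols, tau, age, state_arr, alive, order, rolls,
                   choice_u, p_m, d_rows, d_cols, d_tau):
    """Pure-Python mirror of :func:`tumorca._kernels.ripe_sweep` (same
    randomness consumption, bit-identical results; used for cross-checks)."""
    L = grid.shape[0]
    n = rows.shape[0]
    nd = births = mdeaths = 0
    for k in range(order.shape[0]):
        i = order[k]
        if not alive[i]:
            continue
        r, c = rows[i], cols[i]
        free = []
        for dr in range(-2, 3):
            rr = r + dr
            if rr < 0 or rr >= L:
                continue
            for dc in range(-2, 3):
                if dr == 0 and dc == 0:
                    continue
                cc = c + dc
                if cc < 0 or cc >= L:
                    continue
                if grid[rr, cc] == -1:
                    free.append((rr, cc))
        if not free:
            state_arr[i] = QUIESCENT
            continue
        if p_m >= 0.0 and rolls[k] < p_m:
            alive[i] = False
            grid[r, c] = -1
            mdeaths += 1
            continue
        j = min(int(choice_u[k] * len(free)), len(free) - 1)
        d_rows[nd], d_cols[nd] = free[j]
        d_tau[nd] = tau[i]
        grid[free[j][0], free[j][1]] = n + nd
        nd += 1
        age[i] = 0.0
        state_arr[i] = PROLIFERATING
        births += 1
    return nd, births, mdeaths


def step(
    state: LatticeState,
    config: SimConfig,
    treatment: TreatmentSchedule = NO_TREATMENT,
    rng: np.random.Generator | None = None,
    use_kernel: bool = True,
) -> StepTallies:
    """Advance the state by one tick of length ``config.dt`` (in place)."""
    if rng is None:
        rng = np.random.default_rng()
    t0 = state.t
    dt = config.dt
    random_deaths = 0
    died_pos: list[np.ndarray] = []

    # 1) random-death sweep over ALL alive cells (proliferating and quiescent)
    if treatment.model == "random" and schedule_active(t0, treatment) and state.n_cells:
        p = random_death_prob(treatment.hazard_per_h, dt)
        if p > 0:
            dead = rng.random(state.n_cells) < p
            random_deaths = int(dead.sum())
            if random_deaths:
                died_pos.append(
                    np.column_stack([state.rows[dead], state.cols[dead]])
                )
                state.remove_cells(dead)
                state.random_deaths += random_deaths

    # 2) aging with zero-mean uniform noise, clamped at 0
    n = state.n_cells
    if n:
        if config.age_noise_amp > 0:
            eps = rng.uniform(-config.age_noise_amp, config.age_noise_amp, n)
            np.maximum(0.0, state.age + dt + eps, out=state.age)
        else:
            state.age += dt

    # 3) ripe cells attempt division in a fresh random order
    births = mdeaths = became_quiescent = 0
    ripe = np.flatnonzero(state.age >= state.tau)
    if ripe.size:
        order = rng.permutation(ripe)
        rolls = rng.random(ripe.size)
        choice_u = rng.random(ripe.size)
        mitotic_active = treatment.model == "mitotic" and schedule_active(t0, treatment)
        p_m = float(treatment.p) if mitotic_active else -1.0
        alive = np.ones(n, dtype=bool)
        d_rows = np.empty(ripe.size, dtype=np.int64)
        d_cols = np.empty(ripe.size, dtype=np.int64)
        d_tau = np.empty(ripe.size, dtype=np.float64)
        quiescent_before = int((state.state == QUIESCENT).sum())
        sweep = _kernels.ripe_sweep if use_kernel else _ripe_sweep_py
        nd, births, mdeaths = sweep(
            state.grid, state.rows, state.cols, state.tau, state.age, state.state,
            alive, order, rolls, choice_u, p_m, d_rows, d_cols, d_tau,
        )
        became_quiescent = int((state.state == QUIESCENT).sum()) - quiescent_before
        if mdeaths:
            died_pos.append(
                np.column_stack([state.rows[~alive], state.cols[~alive]])
            )
        # daughter grid indices were written by the sweep relative to the
        # pre-append array length, so append first, then drop the dead
        state.append_cells(
            d_rows[:nd], d_cols[:nd], d_tau[:nd], update_grid=False
        )
        if mdeaths:
            full_mask = np.concatenate([~alive, np.zeros(nd, dtype=bool)])
            state.remove_cells(full_mask)
        state.births += births
        state.mitotic_deaths += mdeaths

    state.t = t0 + dt
    return StepTallies(
        births=births,
        mitotic_deaths=mdeaths,
        random_deaths=random_deaths,
        became_quiescent=became_quiescent,
        died_positions=(
            np.concatenate(died_pos) if died_pos else np.empty((0, 2), dtype=np.int64)
        ),
    )


def edge_reached(state: LatticeState, margin_fraction: float = 0.1) -> bool:
    """True iff any cell lies within ``L * margin_fraction`` sites of a border."""
    if state.n_cells == 0:
        return False
    L = state.geometry.side_sites
    m = L * margin_fraction
    border_dist = np.minimum(
        np.minimum(state.rows, L - 1 - state.rows),
        np.minimum(state.cols, L - 1 - state.cols),
    )
    return bool(border_dist.min() < m)


# -- full runs ---------------------------------------------------------------


def build_initial_state(cfg: RunConfig, rng: np.random.Generator) -> tuple[LatticeState, np.ndarray]:
    """Draw the phenotype pool, assign phenotypes and ages, and seed the
    lattice.  Returns the state and the seeded doubling times."""
    pool = draw_phenotype_pool(
        cfg.phenotype.kind, cfg.phenotype.pool_size, cfg.phenotype.mean_h,
        cfg.phenotype.sd_h, rng,
    )
    tau_min = float(pool.values.min())
    if cfg.engine.dt_h > tau_min:
        raise ValueError(
            f"dt_h={cfg.engine.dt_h} exceeds the shortest doubling time "
            f"{tau_min:.2f} h; a cell would skip a full cycle in one step"
        )
    if cfg.engine.dt_h > tau_min / 10:
        logger.warning(
            "dt_h=%.3g resolves the shortest doubling time (%.3g h) with fewer "
            "than 10 steps per cycle", cfg.engine.dt_h, tau_min,
        )
    phenos = assign_phenotypes(pool, cfg.seeding.n_cells, rng)
    ages = assign_initial_ages(phenos, rng)
    geom = cfg.geometry()
    state = seed_circle(geom, cfg.seeding.radius_um, cfg.seeding.n_cells, phenos, ages, rng)
    return state, phenos


def run_simulation(cfg: RunConfig, use_kernel: bool = True) -> SimulationResult:
    """Run a full simulation from a :class:`RunConfig`.

    The run stops at ``t_max``, on extinction, when a cell reaches the
    edge-margin band of the domain, or (if configured) when the quiescent
    fraction reaches ``stop_quiescent_fraction``.  Fully reproducible from
    ``cfg.seed``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    state, initial_tau = build_initial_state(cfg, rng)
    eng = cfg.engine
    sim = SimConfig(
        dt=eng.dt_h, t_max=eng.t_max_h, age_noise_amp=eng.age_noise_amp_h,
        edge_margin_fraction=eng.edge_margin_fraction,
    )
    sched = cfg.treatment_schedule()

    record_every = int(round(eng.record_interval_h / eng.dt_h))
    snapshot_times = sorted(eng.snapshot_times_h)
    next_snapshot = 0
    died_since_snapshot: list[np.ndarray] = []

    records: list[GrowthRecord] = [GrowthRecord.from_state(state)]
    snapshots: list[Snapshot] = []
    stop_reason = "t_max"
    istep = 0
    while True:
        if state.t >= sim.t_max - 1e-9:
            stop_reason = "t_max"
            break
        if state.n_cells == 0:
            stop_reason = "extinct"
            break
        if edge_reached(state, sim.edge_margin_fraction):
            stop_reason = "edge"
            break
        if (
            eng.stop_quiescent_fraction is not None
            and state.n_cells > 0
            and state.n_quiescent / state.n_cells >= eng.stop_quiescent_fraction
        ):
            stop_reason = "quiescent_stop"
            break
        tallies = step(state, sim, sched, rng, use_kernel=use_kernel)
        istep += 1
        if snapshot_times and tallies.died_positions.size:
            died_since_snapshot.append(tallies.died_positions)
        if istep % record_every == 0:
            records.append(GrowthRecord.from_state(state))
        if (
            next_snapshot < len(snapshot_times)
            and state.t >= snapshot_times[next_snapshot] - sim.dt / 2
        ):
            died = (
                np.concatenate(died_since_snapshot)
                if died_since_snapshot
                else None
            )
            snapshots.append(snapshot_from_state(state, died))
            died_since_snapshot = []
            next_snapshot += 1
        if istep % 100 == 0:
            logger.info(
                "t=%.0f h  n=%d (q=%d)  births=%d deaths=%d+%d",
                state.t, state.n_cells, state.n_quiescent,
                state.births, state.mitotic_deaths, state.random_deaths,
            )

    if records[-1].t < state.t - 1e-9:
        records.append(GrowthRecord.from_state(state))
    logger.info("stopped at t=%.0f h (%s), n=%d", state.t, stop_reason, state.n_cells)
    return SimulationResult(
        records=records,
        snapshots=snapshots,
        initial_doubling_times=np.asarray(initial_tau, dtype=float),
        final_doubling_times=state.tau.copy(),
        stop_reason=stop_reason,
        seed=cfg.seed,
        config=cfg.to_dict(),
    )
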