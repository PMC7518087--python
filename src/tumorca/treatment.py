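"""Treatment-induced death models and schedules.

Two cytotoxicity surrogates are modelled:

* **mitotic death** — a cell-cycle-specific drug: a dividing cell dies with
  probability ``p_m`` at the moment of mitosis (quiescent cells are never
  hit);
* **random death** — a cell-cycle-non-specific drug: every alive cell,
  proliferating or quiescent, dies as a Poisson process with hazard
  ``lambda = (ln 2 / tau) * p_m`` per hour, the rate that matches the
  mitotic probability ``p_m`` through the population growth rate
  ``mu = ln 2 / tau``.

Schedules: ``constant`` (always on), ``single_block`` (on for the first
``on_h`` hours, then off), and ``periodic`` (``n_cycles`` repetitions of
``on_h`` on / ``off_h`` off, then off forever).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "TreatmentSchedule",
    "NO_TREATMENT",
    "equivalent_random_rate",
    "random_death_prob",
    "schedule_active",
    "mitotic_death_roll",
]

MODELS = ("none", "mitotic", "random")
SCHEDULES = ("constant", "single_block", "periodic")


@dataclass(frozen=True)
class TreatmentSchedule:
    """Death model, intensity, and on/off timing law.

    ``p`` is the mitotic death probability for the mitotic model; for the
    random model it is the mitotic-equivalent probability used to derive the
    Poisson hazard via :func:`equivalent_random_rate` (a hazard can also be
    given directly through ``rate_per_h``, which then takes precedence).
    ``ref_tau_h`` is the reference doubling time used in the rate match.
    """

    model: str = "none"
    p: float = 0.0
    schedule: str = "constant"
    on_h: float = 0.0
    off_h: float = 0.0
    n_cycles: int = 1
    ref_tau_h: float = 24.0
    rate_per_h: float | None = None

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown death model {self.model!r}")
        if self.schedule not in SCHEDULES:
            raise ValueError(f"unknown schedule {self.schedule!r}")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must lie in [0, 1]")
        if self.schedule in ("single_block", "periodic") and self.on_h <= 0:
            raise ValueError("on_h must be positive for block/periodic schedules")
        if self.schedule == "periodic" and self.n_cycles < 1:
            raise ValueError("periodic schedule requires n_cycles >= 1")

    @property
    def hazard_per_h(self) -> float:
        """Poisson death hazard (per hour) for the random model."""
        if self.rate_per_h is not None:
            return float(self.rate_per_h)
        return equivalent_random_rate(self.p, self.ref_tau_h)


NO_TREATMENT = TreatmentSchedule(model="none")


def equivalent_random_rate(p_m: float, tau: float) -> float:
    """Poisson hazard (per hour) matching a mitotic death probability ``p_m``.

    ``lambda = mu * p_m`` with ``mu = ln 2 / tau`` the exponential growth
    rate of a population with doubling time ``tau``; the hazard is the
    magnitude of the matched decay rate.
    """
    if not 0.0 <= p_m <= 1.0:
        raise ValueError("p_m must lie in [0, 1]")
    if tau <= 0:
        raise ValueError("tau must be positive")
    return (math.log(2.0) / tau) * p_m


def random_death_prob(rate_per_h: float, dt: float) -> float:
    """Per-step death probability of a Poisson hazard over a step of ``dt`` hours.

    The exact survival form ``1 - exp(-lambda*dt)`` is used rather than the
    first-order ``lambda*dt`` so that results are robust to the step size.
    """
    if rate_per_h < 0:
        raise ValueError("rate must be non-negative")
    if dt <= 0:
        raise ValueError("dt must be positive")
    return -math.expm1(-rate_per_h * dt)


def schedule_active(t: float, schedule: TreatmentSchedule) -> bool:
    """Whether treatment is being applied at time ``t`` (hours)."""
    if t < 0:
        raise ValueError("t must be non-negative")
    if schedule.model == "none":
        return False
    if schedule.schedule == "constant":
        return True
    if schedule.schedule == "single_block":
        return t < schedule.on_h
    # periodic
    period = schedule.on_h + schedule.off_h
    if t >= schedule.n_cycles * period:
        return False
    return (t % period) < schedule.on_h


def mitotic_death_roll(p_m: float, rng: np.random.Generator) -> bool:
    """One Bernoulli(p_m) roll: does this mitosis kill the dividing cell?"""
    if not 0.0 <= p_m <= 1.0:
        raise ValueError("p_m must lie in [0, 1]")
    return bool(rng.random() < p_m)
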