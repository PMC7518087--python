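"""Preset registry for the study scenarios, replicate management, and
cross-replicate aggregation.

Every scenario is run in both a sparse (in-vitro-like) and a dense
(tumor-plane-like) initial configuration and can be combined with any of
the three phenotype-pool kinds (homogeneous, normal, uniform).  Each
experiment is repeated five times by default; replicate k uses seed
``base_seed + k`` and redraws its phenotype pool.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .config import (
    EngineConfig,
    PhenotypeConfig,
    RunConfig,
    SeedingConfig,
    TreatmentConfig,
)
from .engine import run_simulation
from .observables import SimulationResult

__all__ = [
    "ExperimentPreset",
    "list_presets",
    "get_preset",
    "run_replicates",
    "aggregate_curves",
]

logger = logging.getLogger("tumorca")

SPARSE_SEEDING = SeedingConfig(
    mode="sparse", n_cells=5000, radius_um=8000.0, grid_side_sites=1200
)
DENSE_SEEDING = SeedingConfig(
    mode="dense", n_cells=1000, radius_um=400.0, grid_side_sites=600
)

SPARSE_T_MAX = 1200.0
DENSE_T_MAX = 2400.0
BLOCK_ON_H = 120.0  # 5 days
PERIODIC_T_MAX = 1200.0  # five 5-day-on/5-day-off cycles


@dataclass(frozen=True)
class ExperimentPreset:
    """A named scenario; resolve to a full :class:`RunConfig` with
    :meth:`to_config`, choosing the phenotype kind and the seed."""

    name: str
    seeding: SeedingConfig
    treatment: TreatmentConfig
    t_max_h: float
    n_replicates: int = 5

    def to_config(
        self,
        kind: str = "normal",
        seed: int = 0,
        engine: EngineConfig | None = None,
    ) -> RunConfig:
        eng = engine if engine is not None else EngineConfig(t_max_h=self.t_max_h)
        cfg = RunConfig(
            phenotype=PhenotypeConfig(kind=kind),
            seeding=self.seeding,
            engine=eng,
            treatment=self.treatment,
            seed=seed,
        )
        cfg.validate()
        return cfg


def _build_registry() -> dict[str, ExperimentPreset]:
    reg: dict[str, ExperimentPreset] = {}

    def add(name, seeding, treatment, t_max):
        reg[name] = ExperimentPreset(
            name=name, seeding=seeding, treatment=treatment, t_max_h=t_max
        )

    none = TreatmentConfig(model="none")
    add("sparse_untreated", SPARSE_SEEDING, none, SPARSE_T_MAX)
    add("dense_untreated", DENSE_SEEDING, none, DENSE_T_MAX)

    for p in (0.4, 0.5, 0.8):
        add(
            f"sparse_mitotic_p{p}",
            SPARSE_SEEDING,
            TreatmentConfig(model="mitotic", p=p, schedule="constant"),
            SPARSE_T_MAX,
        )
    for p in (0.4, 0.6, 0.8):
        add(
            f"sparse_random_p{p}",
            SPARSE_SEEDING,
            TreatmentConfig(model="random", p=p, schedule="constant"),
            SPARSE_T_MAX,
        )
    for model in ("mitotic", "random"):
        add(
            f"dense_{model}_p0.4",
            DENSE_SEEDING,
            TreatmentConfig(model=model, p=0.4, schedule="constant"),
            DENSE_T_MAX,
        )
        for p in (0.4, 0.8):
            add(
                f"dense_block_{model}_p{p}",
                DENSE_SEEDING,
                TreatmentConfig(model=model, p=p, schedule="single_block", on_h=BLOCK_ON_H),
                DENSE_T_MAX,
            )
        add(
            f"dense_periodic_{model}_p0.8",
            DENSE_SEEDING,
            TreatmentConfig(
                model=model, p=0.8, schedule="periodic",
                on_h=BLOCK_ON_H, off_h=BLOCK_ON_H, n_cycles=5,
            ),
            PERIODIC_T_MAX,
        )
    return reg


_REGISTRY = _build_registry()

#: Short aliases (the mitotic variant is the default reading).
_ALIASES = {
    "dense_block_p0.4": "dense_block_mitotic_p0.4",
    "dense_block_p0.8": "dense_block_mitotic_p0.8",
    "dense_periodic_p0.8": "dense_periodic_mitotic_p0.8",
}


def list_presets() -> list[str]:
    """All registered preset names (aliases included)."""
    return sorted(_REGISTRY) + sorted(_ALIASES)


def get_preset(name: str) -> ExperimentPreset:
    key = _ALIASES.get(name, name)
    try:
        return _REGISTRY[key]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(list_presets())}"
        ) from None


def run_replicates(
    preset_or_config,
    n_replicates: int | None = None,
    base_seed: int = 0,
    kind: str = "normal",
    engine: EngineConfig | None = None,
) -> list[SimulationResult]:
    """Run ``n_replicates`` independent replicates; replicate k uses seed
    ``base_seed + k`` (the phenotype pool is redrawn per replicate).

    Accepts a preset name, an :class:`ExperimentPreset`, or a ready
    :class:`RunConfig` (whose seed field is then overridden per replicate).
    """
    if isinstance(preset_or_config, str):
        preset_or_config = get_preset(preset_or_config)
    if isinstance(preset_or_config, ExperimentPreset):
        n = n_replicates if n_replicates is not None else preset_or_config.n_replicates
        configs = [
            preset_or_config.to_config(kind=kind, seed=base_seed + k, engine=engine)
            for k in range(n)
        ]
    elif isinstance(preset_or_config, RunConfig):
        n = n_replicates if n_replicates is not None else 5
        configs = [preset_or_config.with_seed(base_seed + k) for k in range(n)]
    else:
        raise TypeError("expected a preset name, ExperimentPreset, or RunConfig")
    if n < 1:
        raise ValueError("n_replicates must be >= 1")
    results = []
    for k, cfg in enumerate(configs):
        logger.info("replicate %d/%d (seed %d)", k + 1, n, cfg.seed)
        results.append(run_simulation(cfg))
    return results


def aggregate_curves(
    results: list[SimulationResult], field: str = "n_total"
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pointwise mean and population sd of one growth-record field across
    replicates.

    Replicates that stopped early (edge rule, extinction) are handled by
    truncating all curves to the shortest record grid; the shared grid must
    agree on the recorded times.
    """
    if not results:
        raise ValueError("no results to aggregate")
    n_rec = min(len(r.records) for r in results)
    t = np.array([rec.t for rec in results[0].records[:n_rec]])
    for r in results[1:]:
        ti = np.array([rec.t for rec in r.records[:n_rec]])
        if not np.allclose(ti, t):
            raise ValueError("replicates do not share a common record grid")
    field_map = {
        "n_total": "n_total",
        "n_prolif": "n_proliferating",
        "n_proliferating": "n_proliferating",
        "n_quiesc": "n_quiescent",
        "n_quiescent": "n_quiescent",
        "cum_mitotic_deaths": "cum_mitotic_deaths",
        "cum_random_deaths": "cum_random_deaths",
        "mean_tau": "mean_tau",
        "mean_tau_h": "mean_tau",
        "sd_tau": "sd_tau",
        "sd_tau_h": "sd_tau",
    }
    try:
        attr = field_map[field]
    except KeyError:
        raise ValueError(f"unknown field {field!r}") from None
    mat = np.array(
        [[getattr(rec, attr) for rec in r.records[:n_rec]] for r in results],
        dtype=float,
    )
    return t, mat.mean(axis=0), mat.std(axis=0, ddof=0)
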