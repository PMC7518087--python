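"""Structured run configuration and YAML round-trip.

A :class:`RunConfig` fully determines a simulation (together with its RNG
seed): phenotype-pool parameters, seeding geometry, engine step settings,
and the treatment schedule.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields, replace

import yaml

from .state import Geometry
from .treatment import TreatmentSchedule

__all__ = [
    "PhenotypeConfig",
    "SeedingConfig",
    "EngineConfig",
    "TreatmentConfig",
    "RunConfig",
]


@dataclass(frozen=True)
class PhenotypeConfig:
    """Doubling-time pool parameters (defaults: 500 phenotypes, mean 24 h,
    sd 4.8 h)."""

    kind: str = "normal"  # normal | uniform | homogeneous
    mean_h: float = 24.0
    sd_h: float = 4.8
    pool_size: int = 500


@dataclass(frozen=True)
class SeedingConfig:
    mode: str = "sparse"  # sparse | dense
    n_cells: int = 5000
    radius_um: float = 8000.0
    grid_side_sites: int = 1200
    site_um: float = 20.0


@dataclass(frozen=True)
class EngineConfig:
    dt_h: float = 1.0
    t_max_h: float = 1200.0
    age_noise_amp_h: float = 0.1
    record_interval_h: float = 4.0
    snapshot_times_h: tuple[float, ...] = ()
    edge_margin_fraction: float = 0.1
    #: optional early stop once the quiescent fraction reaches this value
    stop_quiescent_fraction: float | None = None


@dataclass(frozen=True)
class TreatmentConfig:
    model: str = "none"  # none | mitotic | random
    p: float = 0.0
    schedule: str = "constant"  # constant | single_block | periodic
    on_h: float = 0.0
    off_h: float = 0.0
    n_cycles: int = 1
    ref_tau_h: float = 24.0
    rate_per_h: float | None = None


@dataclass(frozen=True)
class RunConfig:
    phenotype: PhenotypeConfig = field(default_factory=PhenotypeConfig)
    seeding: SeedingConfig = field(default_factory=SeedingConfig)
    engine: EngineConfig = field(default_factory=EngineConfig)
    treatment: TreatmentConfig = field(default_factory=TreatmentConfig)
    seed: int = 0

    # -- derived objects ----------------------------------------------------

    def geometry(self) -> Geometry:
        return Geometry(
            side_sites=self.seeding.grid_side_sites, site_um=self.seeding.site_um
        )

    def treatment_schedule(self) -> TreatmentSchedule:
        tc = self.treatment
        if tc.model == "none":
            return TreatmentSchedule(model="none")
        return TreatmentSchedule(
            model=tc.model,
            p=tc.p,
            schedule=tc.schedule,
            on_h=tc.on_h,
            off_h=tc.off_h,
            n_cycles=tc.n_cycles,
            ref_tau_h=tc.ref_tau_h,
            rate_per_h=tc.rate_per_h,
        )

    def validate(self) -> None:
        """Reject invalid combinations before a run starts."""
        eng = self.engine
        if eng.dt_h <= 0:
            raise ValueError("dt_h must be positive")
        if eng.t_max_h <= 0:
            raise ValueError("t_max_h must be positive")
        if eng.age_noise_amp_h < 0:
            raise ValueError("age_noise_amp_h must be non-negative")
        if eng.record_interval_h <= 0:
            raise ValueError("record_interval_h must be positive")
        ratio = eng.record_interval_h / eng.dt_h
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("record_interval_h must be a multiple of dt_h")
        if not 0 < eng.edge_margin_fraction < 0.5:
            raise ValueError("edge_margin_fraction must lie in (0, 0.5)")
        if eng.stop_quiescent_fraction is not None and not (
            0 < eng.stop_quiescent_fraction <= 1
        ):
            raise ValueError("stop_quiescent_fraction must lie in (0, 1]")
        if self.seeding.mode not in ("sparse", "dense"):
            raise ValueError("seeding.mode must be 'sparse' or 'dense'")
        if self.seeding.n_cells < 1:
            raise ValueError("seeding.n_cells must be >= 1")
        self.geometry().check_fits_circle(
            self.seeding.radius_um, eng.edge_margin_fraction
        )
        self.treatment_schedule()  # raises on invalid treatment combinations

    # -- (de)serialisation --------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["engine"]["snapshot_times_h"] = list(self.engine.snapshot_times_h)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        def build(dc_cls, section):
            known = {f.name for f in fields(dc_cls)}
            unknown = set(section) - known
            if unknown:
                raise ValueError(f"unknown {dc_cls.__name__} keys: {sorted(unknown)}")
            return dc_cls(**section)

        eng = dict(d.get("engine", {}))
        if "snapshot_times_h" in eng:
            eng["snapshot_times_h"] = tuple(eng["snapshot_times_h"])
        return cls(
            phenotype=build(PhenotypeConfig, d.get("phenotype", {})),
            seeding=build(SeedingConfig, d.get("seeding", {})),
            engine=build(EngineConfig, eng),
            treatment=build(TreatmentConfig, d.get("treatment", {})),
            seed=int(d.get("seed", 0)),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def with_seed(self, seed: int) -> "RunConfig":
        return replace(self, seed=int(seed))
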