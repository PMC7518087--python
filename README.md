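# tumorca

A 2D on-lattice cellular-automaton model of tumor growth with heritable
proliferation phenotypes, space-driven reversible quiescence, and two
contrasting cell-kill mechanisms (death at mitosis vs. death at random
times). The package exists to study a question from theoretical oncology:
**when a drug kills the same *fraction* of cells, does it matter *when* in
the cell cycle it kills them?** In this model it matters a great deal —
mitotic killers select for slowly cycling cells and delay regrowth, while
time-independent killers thin the tumor, release contact inhibition, and
select for the fastest phenotypes.

## The model

Cells live on a square lattice of 20 µm sites, at most one cell per site.
Each cell *i* carries a heritable doubling time τᵢ drawn from a finite
phenotype pool (500 values) and an age *aᵢ*.

* **Phenotype pools** — homogeneous (all τ = 24 h), normal 𝒩(24 h, 4.8 h)
  (redrawn if below 1 h), or uniform 𝒰(15.7 h, 32.3 h); the uniform bounds
  are mean ± sd·√3, so both heterogeneous pools share mean and variance.
* **Aging** — each step of Δt = 1 h, every live cell ages by
  Δt + ξ, ξ ~ 𝒰(−0.1, 0.1) h (desynchronization noise), clamped at 0.
* **Division** — when *aᵢ* ≥ τᵢ the cell attempts division into a uniformly
  chosen free site of its 2-Moore neighborhood (Chebyshev distance ≤ 2,
  up to 24 sites). Both daughters inherit τᵢ and restart at age 0.
* **Quiescence** — if no neighboring site is free the cell becomes
  quiescent, keeping its age; it re-attempts division every step and
  resumes the moment space opens (reversible contact inhibition).
* **Treatment** — two death models with matched expected kill:
  * *mitotic*: at each division attempt with free space, the cell dies with
    probability p_m instead of dividing;
  * *random*: every live cell (cycling or quiescent) dies with hazard
    λ = (ln 2 / τ)·p_m, applied per step as 1 − exp(−λΔt).

  Schedules: `constant`, `single_block` (e.g. first 120 h), or `periodic`
  (e.g. 120 h on / 120 h off for 5 cycles). Dead cells lyse instantly,
  freeing their site.
* **Seeding** — `sparse`: 5,000 cells scattered in an 8 mm-radius circle
  (~1% of sites); `dense`: 1,000 cells in a 0.4 mm circle (~80%).
  Initial ages are Uniform[0, τᵢ).

Simulations stop at `t_max`, on extinction, or when the colony approaches
the lattice edge (within 10% of the side length).

## Worked example

```python
from tumorca import (
    RunConfig, PhenotypeConfig, SeedingConfig, EngineConfig, TreatmentConfig,
    run_simulation, quiescence_onset,
)

cfg = RunConfig(
    phenotype=PhenotypeConfig(kind="normal", mean_h=24.0, sd_h=4.8, pool_size=500),
    seeding=SeedingConfig(mode="sparse", n_cells=600, radius_um=2500.0,
                          grid_side_sites=400),
    engine=EngineConfig(dt_h=1.0, t_max_h=300.0, record_interval_h=8.0),
    treatment=TreatmentConfig(),          # untreated
    seed=42,
)
result = run_simulation(cfg)

df = result.records_dataframe()
print(df.tail(3).to_string(index=False))
print("stop reason:", result.stop_reason)
print("quiescence onset (1%):", quiescence_onset(result.records, 0.01), "h")
print("mean doubling time: %.2f -> %.2f h"
      % (df.mean_tau_h.iloc[0], df.mean_tau_h.iloc[-1]))
```

Output:

```text
  t_h  n_total  n_prolif  n_quiesc  cum_mitotic_deaths  cum_random_deaths  mean_tau_h  sd_tau_h
288.0    61255      3837     57418                   0                  0   20.973972  4.573050
296.0    61884      3861     58023                   0                  0   20.954442  4.568401
300.0    62327      3870     58457                   0                  0   20.942524  4.562035
stop reason: t_max
quiescence onset (1%): 88.0 h
mean doubling time: 24.05 -> 20.94 h
```

Even without treatment the mean doubling time drifts down (24.1 → 20.9 h):
space competition alone selects for fast cyclers.

## Command line

```bash
tumorca list-presets                        # named study scenarios
tumorca run sparse_untreated --kind normal --replicates 5 --seed 1 --out out/
tumorca run --config my_config.yaml --out out/
tumorca aggregate out/ --field n_total      # mean ± sd across replicates
tumorca plot out/ --field n_total           # PNG growth curves
```

`run` writes per-replicate growth curves (`growth_repK.csv`), initial and
final doubling-time histograms, run metadata (`meta_repK.yaml`), and
lattice snapshots at configured times. Presets cover the full study grid:
sparse/dense seeding × {untreated, mitotic, random} × {constant,
single-block, periodic} schedules at several kill probabilities.

## Layout

| Module | Contents |
| --- | --- |
| `tumorca.phenotypes` | doubling-time pools and assignment |
| `tumorca.seeding` | circular seeding geometries and initial ages |
| `tumorca.engine` | the simulation step, stop conditions, run loop |
| `tumorca._kernels` | numba-compiled division sweep |
| `tumorca.treatment` | death models and schedules |
| `tumorca.observables` | growth records, onset/rate/histogram/snapshot analysis |
| `tumorca.experiments` | named presets, replicate running, aggregation |
| `tumorca.cli` | `tumorca` command-line interface |
| `tumorca.config` | dataclass configs with YAML round-trip |

See `docs/methods.md` for the full model description, parameter table, and
numerical notes.
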