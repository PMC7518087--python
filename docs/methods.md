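# Methods

## 1. Model definition

### 1.1 Lattice and state

The domain is an L × L square lattice of sites with side 20 µm (one cell
diameter); each site holds at most one cell. A cell is the tuple
(row, col, τ, age, state) where τ is its heritable doubling time (h), age
its clock since last division (h), and state ∈ {proliferating, quiescent}.
Internally the population is stored as parallel numpy arrays plus an
occupancy grid mapping each site to the cell index occupying it (−1 if
free); the bijection between the two is asserted by `LatticeState.validate()`.

### 1.2 Phenotype pools

A pool of `pool_size` = 500 doubling times is drawn once per run:

* `homogeneous` — all values equal to `mean_h`;
* `normal` — 𝒩(mean_h, sd_h), values ≤ 1 h redrawn (a doubling time must be
  positive and resolvable by the time step);
* `uniform` — 𝒰(mean_h − sd_h·√3, mean_h + sd_h·√3), which has exactly the
  requested mean and standard deviation. With mean 24 h and sd 4.8 h the
  bounds are 15.7–32.3 h.

Each seeded cell receives a pool value uniformly **with replacement**, and
daughters inherit the mother's τ exactly, so selection acts on standing
variation only (no mutation).

### 1.3 Update step

One step advances time by Δt (default 1 h) in three phases:

1. **Random death** (if the `random` model is active and the schedule is
   on): every live cell dies independently with probability
   1 − exp(−λΔt), λ = (ln 2 / τ)·p. Dead cells are removed immediately
   (instant lysis) and their sites freed.
2. **Aging**: every remaining cell's age increases by Δt + ξ,
   ξ ~ 𝒰(−`age_noise_amp`, +`age_noise_amp`) (default 0.1 h), clamped at 0.
   The noise desynchronizes lineages that would otherwise divide in
   lock-step forever.
3. **Division sweep**: cells with age ≥ τ ("ripe") are visited in a fresh
   uniformly random permutation. Each ripe cell counts the free sites of
   its 2-Moore neighborhood (Chebyshev distance ≤ 2, ≤ 24 sites):
   * no free site → the cell is marked quiescent (age retained; it is
     re-examined every subsequent step and divides as soon as space opens);
   * free sites exist and the `mitotic` model is active with the schedule
     on → with probability p the cell dies instead of dividing;
   * otherwise the cell divides into a uniformly chosen free site; both
     daughters carry the mother's τ and restart at age 0, in the
     proliferating state.

   Within one sweep, sites filled by earlier divisions are unavailable to
   later cells — the random visiting order makes this competition fair.

The two death routes are calibrated to the same expected kill per cell
cycle: a cycling cell with doubling time τ faces one Bernoulli(p) trial per
cycle under the mitotic model, and an exponential hazard (ln 2/τ)·p under
the random model, whose per-cycle kill probability is 1 − 2^(−p) ≈ p·ln 2
— equal fractions killed, at different points of the cycle and with
different exposure of quiescent cells (the random model reaches them, the
mitotic model cannot).

### 1.4 Treatment schedules

* `constant` — active for the whole run;
* `single_block` — active for t < `on_h` (default 120 h), then off;
* `periodic` — `n_cycles` repetitions of `on_h` on / `off_h` off
  (default 120/120 × 5), off afterwards.

Activity is evaluated at the current simulation time each step.

### 1.5 Seeding

Cells are placed uniformly at random (without collision) among the lattice
sites whose centers lie within a circle around the lattice center:

* `sparse` — 5,000 cells in an 8 mm-radius circle ≈ 1.0% occupancy
  (502,625 in-circle sites): isolated cells growing into colonies;
* `dense` — 1,000 cells in a 0.4 mm-radius circle ≈ 80% occupancy
  (1,257 sites): a pre-formed, contact-inhibited tumor mass.

Initial ages are Uniform[0, τᵢ), i.e. each cell starts at a uniformly
random point of its own cycle.

### 1.6 Stop conditions

A run ends at `t_max_h`, on extinction, when any cell comes within
`edge_margin_fraction`·L (default 10%) of the lattice border (growth would
become boundary-artifacted), or — optionally — once the recorded quiescent
fraction exceeds `stop_quiescent_fraction` (a compute-saving truncation for
onset measurements; it never changes any value recorded before it fires).

## 2. Parameters

| Parameter | Default | Units | Rationale |
| --- | --- | --- | --- |
| site size | 20 | µm | one tumor-cell diameter |
| Δt (`dt_h`) | 1 | h | resolves a 24 h cycle in 24 steps; see §3.1 |
| mean doubling time `mean_h` | 24 | h | typical fast-growing tumor cell line |
| sd of pool `sd_h` | 4.8 | h | mean/5; gives the 15.7–32.3 h uniform bounds |
| pool size | 500 | — | finite standing variation for selection |
| minimum τ | 1 | h | redraw bound for the normal pool |
| age noise amplitude | 0.1 | h | breaks division synchrony; ≪ Δt |
| sparse seeding | 5,000 cells / 8 mm | — | ~1% occupancy, isolated colonies |
| dense seeding | 1,000 cells / 0.4 mm | — | ~80% occupancy, solid mass |
| sparse lattice side | 1,200 | sites | 24 mm; see §3.2 |
| dense lattice side | 600 | sites | 12 mm, ample room for regrowth |
| edge margin | 0.1·L | sites | stop before boundary effects |
| kill probability p | 0.4–0.8 | — | sub-lethal to supra-lethal per-cycle kill |
| block / period length | 120 | h | five days on (and five off per cycle) |
| record interval | 4–8 | h | growth-curve resolution |
| quiescence-onset threshold | 0.01 | fraction | see §3.3 |

## 3. Numerical choices

### 3.1 Time step

The hard validity bound is Δt ≤ min(τ) over the drawn pool — a coarser
step could skip an entire cell cycle. A warning (not an error) is logged
when Δt > min(τ)/10, because a 500-draw normal pool with sd 4.8 h
routinely contains values below 10 h, yet Δt = 1 h still resolves them in
≥ 5–10 steps and halving Δt changes measured growth rates by < 5%
(asserted in `tests/test_engine_properties.py::test_rate_insensitive_to_dt`).
Cell ages, not a global clock, carry the cycle, so discretization error
appears only as a ≤ Δt delay of each division.

### 3.2 Lattice sizes

The sparse scenario uses L = 1,200 (24 mm) rather than the minimal
L = 1,000 that would contain the 8 mm seeding circle: with L = 1,000 the
circle plus the 10% edge margin fit with zero slack, so a seed on the rim
triggers the edge stop within a few divisions. L = 1,200 gives every rim
colony ~1.8 mm of growth room. The dense scenario's L = 600 is generous
(the 0.4 mm mass can grow 60-fold in radius).

### 3.3 Quiescence onset

Onset is defined as the first *recorded* time the quiescent fraction
reaches 1%. The threshold is exposed (`quiescence_onset(records,
threshold)`) because the value is definition-sensitive: in the untreated
sparse scenario the fraction passes 1% at ≈ 75–90 h (seed-dependent),
2% near 85 h, and 5–8% by 100 h — quiescence becomes *visually* dominant
in snapshots considerably after the 1% crossing. Measurements quote the
threshold used. The 4 h record interval quantizes the onset by at most one
interval.

### 3.4 Growth-rate estimation

`fit_growth_rate` is a least-squares slope of ln n(t) over a stated
window. For post-treatment comparisons, `fit_rate_after_crossing(records,
n_ref, duration)` anchors the window at the time each curve first reaches
a common population size (e.g. 1,500 cells) — treated populations restart
from very different depths, and comparing slopes at a matched size avoids
conflating regrowth speed with the free-space regime the population
happens to be in.

### 3.5 Reduced problem sizes in tests

The test suite runs several analyses at reduced scale chosen by this
package (600 seeded cells in a 2.5 mm circle for selection-direction
tests; 10–50 cells for branching-process oracles) so the full suite
finishes in well under a minute of simulation per test. These scaled
scenarios keep the defining ratios of the full ones (≈1% occupancy,
identical pool and Δt); full-scale runs back the headline quantities in
`scripts/acceptance.py` and `tests/test_acceptance.py`.

### 3.6 Determinism and the compiled kernel

All randomness flows from one `numpy.random.default_rng(seed)` per run.
The division sweep is numba-compiled for speed; it consumes *pre-drawn*
arrays (visit permutation, death rolls, site-choice uniforms), so a pure
Python reference implementation consumes the identical stream and is
asserted bit-identical over multi-step runs
(`test_kernel_matches_python_reference`). Full-scale sparse runs take
~1–3 s.

## 4. What the model does and does not represent

The simulation is a minimal mechanistic caricature, not a calibrated
digital twin. It represents: space competition on a rigid monolayer-like
lattice, heritable proliferation-rate heterogeneity, reversible
contact-inhibited quiescence, and the cell-cycle specificity of drug kill.
It deliberately omits: nutrient/oxygen fields and necrosis, cell motility
and pushing, mutation or phenotype drift, pharmacokinetics (schedules are
on/off boxes), three-dimensional growth, immune interaction, and
death-by-crowding. Consequences to keep in mind:

* absolute times (e.g. the ~80 h quiescence onset) scale directly with the
  assumed 24 h mean cycle and the seeding density;
* selection is purely among pre-existing clones — with mutation, random
  killing would accelerate adaptation even further;
* quiescent cells are immortal in the untreated model; real quiescent
  cores eventually die, which would free space and weaken the selection
  pressure measured here;
* lattice rigidity makes contact inhibition maximally strict; motile or
  deformable cells would delay quiescence onset.

## 5. Limitations

* Onset times carry a one-record-interval quantization and a seed-to-seed
  sd of a few hours; five replicates give a sub-5 h standard error.
* The mitotic death model only tests cells that have space to divide;
  a fully enclosed population is untouchable by it (by design — this is
  the mechanism under study), so constant-mitotic runs at high p can
  stall into near-static quiescent configurations rather than go extinct.
* The 2-Moore neighborhood allows a daughter to "skip over" an occupied
  ring of width 1; this mild non-locality is part of the model definition,
  not an approximation choice.
* Performance relies on numba; set `use_kernel=False` in
  `run_simulation`/`step` to run the pure-Python path (identical results,
  ~50× slower).
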