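# Methods

## Scope and modelling stance

`ricespace` answers one question: at what uniform square spacing does a
rice stand maximise grain biomass per unit ground area? The canopy model is
deliberately a *surrogate*: it keeps the process chain that makes spacing
matter — light interception that saturates with local leaf-area density,
photosynthesis, temperature-sensitive maintenance, sink-strength carbon
allocation, thermal-time phenology — and drops everything that does not
change the sign of those gradients (3-D organ geometry, ray tracing, light
quality signalling, tillering plasticity, remobilisation from leaves to
grain). Biomass is carried in abstract mol of assimilate (CH₂O
equivalents); no attempt is made to reproduce any calibrated cultivar, and
the absolute fitness scale is therefore arbitrary. What the package claims
is the *shape* of the response: per-plant light and grain increase with
spacing, border plants out-yield inner ones, and areal yield has a single
interior optimum.

## Canopy simulator

**State.** A `rows × cols` lattice (default 6 × 6) of plants at spacing `s`
cm. Each plant carries a set of organs (leaf, grain; internode and root are
supported organ types but not scheduled by default), a carbon pool, and
cumulative ledgers for assimilation, maintenance paid, and growth
respiration. Development is canopy-level: all plants share one thermal-time
clock and one organ schedule; only organ biomass differs between plants.

**Light.** The ground plane (lattice extent plus a 2σ margin) is gridded
into 2-cm cells. Plant *i* deposits leaf area *L*ᵢ through an isotropic
Gaussian of spread σᵢ = 0.35·√*L*ᵢ (floored at 5 cm), truncated at 4σ and
renormalised so the deposit totals *L*ᵢ. A cell with leaf-area density λ
absorbs the fraction 1 − exp(−k·λ) of its incident PAR (k = 0.6) and the
absorbed amount is split among depositors in proportion to their share of
λ. Consequences worth knowing: total absorption can never exceed the PAR
incident on the gridded area; overlapping footprints shade each other
through the concavity of the exponential (the density → shading gradient);
and plants at the perimeter always see unoccupied cells, which produces the
border effect that motivates scoring inner plants only.

**Carbon.** Daily, per plant: pool += RUE × absorbed (RUE = 0.06 mol
biomass per mol photons); maintenance 0.01·B·2^((T−25)/10) is paid from the
pool, floored at zero — an unpaid remainder simply suppresses that day's
growth (no biomass loss; the simplest rule that keeps biomass
non-negative). The remaining pool is distributed over active sinks
proportionally to relative sink strength (leaf 1.0, grain 3.0; internode
0.7 and root 0.5 if present), each increment taxed 25 % growth respiration.
With no active sink the pool carries over. Carbon is conserved exactly:
initial biomass + Σ assimilation = standing biomass + growth respiration +
maintenance paid + residual pools, and the test suite enforces a relative
residual ≤ 1e-9 *every day*, not only at season end.

**Sinks and potential organ size.** An organ is an active sink while its
thermal age is below 300 °Cd and the canopy is pre-maturity, *and* while it
is below its potential size (leaf 0.004, grain 0.5, internode/root
0.02 mol). The potential-size gate is essential and deserves its rationale
spelled out: because the footprint spreads as √L, an uncrowded plant's
absorbed light scales linearly with its leaf area, so a model with
unbounded organ growth grows exponentially until flowering — hundred-mol
plants, grotesque border effects, and no interior optimum of areal yield.
A fixed potential organ dimension is the standard sink-source assumption
and is what creates the saturating leaf area (≈ 2000 cm² per plant) that
the spacing response hinges on. Allocation is clipped at the remaining
capacity; the surplus stays in the pool for the next day.

**Phenology.** Thermal time above T_base = 8 °C; one new leaf per tiller
(12 tillers, fixed) at every 100 °Cd phyllochron crossing before flowering
at 1200 °Cd; one grain organ per tiller at flowering; all demand ends at
maturity, 1800 °Cd. Organs are stamped with the threshold crossing as their
initiation time, which makes development independent of the daily step
size.

**Stochasticity.** The only random element is an optional ±5 % seeded
jitter of initial plant biomass, mimicking transplant heterogeneity. Its
effect on the areal fitness of a default stand is small (relative sd
≈ 0.3 %), which is what lets a swarm optimizer resolve the optimum to a few
millimetres.

## Fitness

fitness = Σ(inner grain) / (n_inner · s²). Each inner plant is attributed
an s × s ground cell, so the measure is independent of lattice size for a
uniform stand; border plants are excluded because their lateral light
surplus is an artefact of the finite lattice, not of the spacing. This area
convention sets the absolute scale of all fitness values the package
reports.

## Optimizer

A 1-D particle swarm (default 20 particles, 300 iterations, bounds
[5, 50] cm, velocity cap 0.2 × range) in two stages split at a switching
point drawn uniformly from [75, 225]:

* before the switch: inertia-weight update with
  ω(t) = 0.9 − 0.5·ln t / ln t_max — a log of base t_max, so ω sweeps the
  classic 0.9 → 0.4 (clamped for safety);
* from the switch on: constriction update with φ = 0.729.

Learning factors c₁ = c₂ = 2.0 and φ = 0.729 are the canonical PSO
constants; all are exposed in config. Disturbances:

* *first-order*, gated per particle per iteration by
  pr(k) = cos(πk/2t_max)/2 (0.5 at start, 0 at the end): one uniformly
  chosen rule from the active stage's set — exploration-stage rules rescale
  x by r, (r₁+r₂)·r₃, a standard-normal draw, or reset x uniformly within
  bounds; convergence-stage rules contract x by r or (r₁+r₂)/2. Results are
  clipped into bounds, velocity preserved. The undeclared scale factor of
  the first rule is treated as U(0, 1) like its siblings.
* *second-order*, when the global best has improved by less than a 1e-9
  relative tolerance for 10 consecutive iterations: every particle jumps to
  (g₋₂+g₋₁)·ra, ra ~ U(−2, 2) per particle, with g₋₂, g₋₁ the two most
  recent global-best positions (a literal reading would need a future
  generation's best, which does not exist at decision time; the two most
  recent bests are the nearest well-defined quantity, and the single best
  is used twice when history is shorter).

Boundary handling is clip-with-velocity-zeroing. Stochastic objectives get
a per-evaluation seed derived from (run seed, iteration, particle index),
so runs are bit-reproducible; with disturbances disabled and a constant ω
the algorithm reduces exactly — trajectory-for-trajectory — to canonical
inertia-weight PSO, which the suite verifies against an independently
written reference.

## Synthetic climate

The generator emulates a subtropical lowland season: PAR and temperature
follow one full cosine cycle (trough at the season edges, peak mid-season)
with means 35 mol m⁻² d⁻¹ and 25 °C and amplitudes 10 and 5; day length
sweeps 11–14 h on the same cycle. Noise is mean-one lognormal (σ = 0.15)
multiplicative on PAR and additive normal (σ = 1.5 °C) on temperature,
clipped to valid ranges. The full-cycle shape makes the envelope mean equal
the configured mean exactly, which pins down the generator's calibration in
closed form. Season length is not dictated by the method and defaults to
120 days (transplant to harvest). What the generator does **not** emulate:
weather autocorrelation, monsoon cloud runs, typhoon events, or any
site-specific record — so passing tests demonstrate the machinery's
correctness and the qualitative spacing response, not a prediction for any
real site or year.

## Numerical choices and problem sizes

* Ground grid 2 cm; a 0.5-cm re-evaluation agrees within 2 % (tested).
* Footprints truncated at 4σ and renormalised; windows share one size per
  day so they vectorise.
* Potential-size clipping can overshoot an organ's cap by at most one day's
  share; the organ stops drawing the next day.
* The fast profile (5 × 5 lattice scored on its inner 3 × 3, 10 particles,
  50 iterations, switching range [13, 38]) is the package's default for
  repeated-run experiments and CI; the full 6 × 6 / 300-iteration setup is
  the default for single runs. With default parameters a 6 × 6 season takes
  ~0.1 s, a fast-profile optimization ~30 s.
* Equality-sensitive I/O (climate tables, traces) writes floats at repr
  precision and reads with round-trip parsing, so write→read is the
  identity.

## Known limitations

* The fitness scale (mol cm⁻²) is not comparable to field yields; only the
  location and shape of the optimum are meaningful. With the default
  cultivar the optimum sits near 7–8 cm — denser than the 15–20 cm typical
  of transplanted rice — because the surrogate's fixed 12-tiller plants
  saturate at a modest leaf area; cultivar parameters shift the optimum but
  the unimodal shape is robust.
* One cultivar, no genotype coupling; tiller number and organ potentials
  fixed; no height growth, so no asymmetric competition for direct beam.
* Light is daily and two-dimensional: no solar geometry, no within-day
  dynamics, no row-orientation effects (inter-row = inter-plant by
  construction).
* The stand is a small lattice with border exclusion; very large-stand
  behaviour is extrapolated, not simulated.
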