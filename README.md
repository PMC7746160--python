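# ricespace

Finding the inter-plant spacing that maximises grain yield per unit ground
area in a rice stand, by coupling a functional-structural canopy surrogate
to a mixed particle swarm optimizer (MPSO) with multistage disturbances.

Plant spacing controls the light microclimate of a stand: tighter spacing
closes the canopy early and wastes assimilate on mutual shading and
maintenance of surplus leaf mass, while wider spacing leaves ground — and
light — unused. Field trials over a spacing gradient are slow and expensive;
`ricespace` replaces them with a daily simulation of a plant lattice and a
global optimizer robust to local optima. The package is aimed at crop
modellers and students of simulation-based optimization who want a fully
self-contained, reproducible testbed for spacing/density questions.

## The model and the objective

A stand of `rows × cols` plants on a square lattice with spacing *s* (cm,
inter-row = inter-plant) grows through a daily loop driven by incident PAR
*I* (mol m⁻² d⁻¹), mean temperature *T* and thermal time
*tt* = Σ max(0, *T* − *T*_base):

1. **Light interception** — each plant deposits its leaf area
   *L*ᵢ = SLA · (leaf biomass) onto a 2-cm ground grid through an isotropic
   Gaussian footprint (σᵢ = 0.35·√*L*ᵢ, min 5 cm). A cell with leaf-area
   density λ absorbs the Beer–Lambert fraction 1 − e^(−k·λ) of its incident
   PAR, split among contributing plants by their share of λ.
2. **Photosynthesis** — *A*ᵢ = RUE · (absorbed PAR)ᵢ into a per-plant carbon
   pool.
3. **Maintenance respiration** — *m*·*B*ᵢ·Q₁₀^((T−25)/10), paid from the
   pool first (a shortfall suppresses that day's growth).
4. **Allocation** — the remaining pool is shared among active sink organs
   (leaves pre-flowering, grains after) in proportion to relative sink
   strength, net of a 25 % growth-respiration levy; organs stop drawing once
   they reach their potential size.
5. **Development** — one new leaf per tiller per phyllochron crossing before
   flowering (*tt* < 1200 °Cd), one grain per tiller at flowering, all sinks
   closed at maturity (1800 °Cd).

The objective (fitness) is areal grain yield over the **inner** plants only
— perimeter plants enjoy a lateral light surplus (border effect) and are
discarded:

```
fitness(s) = Σ inner grain biomass / (n_inner · s²)      [mol cm⁻²]
```

## The optimizer

MPSO is a 1-D particle swarm over *s* ∈ [5, 50] cm with two stages split at
a switching point *T* drawn from [75, 225] (300 iterations total):

* inertia-weight update ω·v + c₁r₁(p−x) + c₂r₂(g−x) before *T*, with
  ω = 0.9 − 0.5·ln(t)/ln(t_max); constriction update φ·(v + …), φ = 0.729,
  after *T*;
* **first-order disturbance**: with probability cos(πk/2t_max)/2 a particle
  is re-positioned by a random rule — aggressive rescalings or a full reset
  in the exploration stage, mild contractions in the convergence stage;
* **second-order disturbance**: after 10 stagnant iterations every particle
  is thrown to (g₋₂ + g₋₁)·ra, ra ~ U(−2, 2), around the two most recent
  global bests.

Every simulation and every optimizer run is exactly reproducible from its
seed.

## Worked example

```bash
$ ricespace optimize --fast --seed 0
best spacing: 6.65 cm  fitness: 0.0155718 mol/cm^2  (t_switch=35)

$ ricespace scan --fast --step 0.5 --out scan.csv
argmax: 6.50 cm  fitness: 0.0155515
```

The optimizer's best spacing (6.65 cm) sits within half a centimetre of the
brute-force grid-scan argmax (6.5 cm) — the swarm found the interior optimum
of the fitness curve, which rises from 5 cm (over-crowded: early canopy
closure, heavy mutual shading and maintenance load), peaks near 7 cm, and
falls off toward 50 cm as ground area grows faster than per-plant grain.
Repeated runs with different seeds agree to a few millimetres. A single
season at a fixed spacing:

```bash
$ ricespace simulate --spacing 18.3
{
  "spacing_cm": 18.3,
  "grain_biomass_mol": 41.387…,
  "area_cm2": 5358.24,
  "fitness_mol_per_cm2": 0.0077240…
}
```

All commands accept `--config config.yaml` with sections
`climate/cultivar/lattice/mpso`; `ricespace climate synth` writes reusable
climate tables.

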