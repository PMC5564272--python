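# Methods

`dropevo` simulates populations of aqueous water-in-oil microdroplets that
compete for material through the continuous oil phase and are driven through
recursive cycles of growth, size selection, feedstock replenishment and
division. This note documents the model, its assumptions, the default
parameters and why they were chosen, and what the synthetic experiments do
and do not demonstrate.

## Physical model

### Geometry and units

Droplets are spheres described by radius *r* (µm); volume V = (4/3)πr³ (µm³),
surface area A = 4πr² (µm²), diameter D = 2r. Solute contents are absolute
amounts in mol; concentrations are reported in mol/L (1 µm³ = 10⁻¹⁵ L).
Time is in seconds. These conventions are fixed throughout.

### Osmotic water exchange

Each droplet's osmolarity is Π = Σₖ nₖ/V over the osmotically active
species. Water moves between droplets down the osmotic gradient. Rather
than resolving the packed-monolayer geometry, the chamber is treated as a
**mean-field bath**: every droplet exchanges with the area-weighted
population mean,

    dV_i/dt = k_w · A_i · (Π_i − Π̄),   Π̄ = Σⱼ A_j Π_j / Σⱼ A_j.

The area weighting makes the fluxes sum to zero identically, so total
volume is conserved by construction (observed drift ≈ 10⁻¹² relative over
10⁴ steps, from float rounding only). The permeability k_w is in
µm·L·mol⁻¹·s⁻¹ (volume flux per unit area per unit osmolarity difference);
default 0.01. The mean-field simplification discards spatial structure:
it cannot produce local coarsening patterns, only population-level
redistribution, which is the quantity the polydispersity readout tracks.

### Solute exchange and the inverse molecular-weight law

Dissolved species permeate between droplets at a rate inversely
proportional to molecular weight. For an exchangeable species k,

    dn_ik/dt = k_s · (mw_ref / MW_k) · A_i · (c̄_k − c_ik),

with the same area-weighted mean concentration c̄ₖ, k_s = 0.001 µm/s at
the reference molecular weight mw_ref = 100 g/mol. Non-exchangeable
(trapped) species have identically zero flux. Per-species totals are
conserved by the same argument as volume.

A practical consequence that shapes everything downstream: the
concentration-relaxation time of a droplet is τ ≈ (r/3)/(k_s·mw_ref/MW).
For a 132 g/mol monomer this is ≈ 2600 s at r = 6 µm but ≈ 13000 s at
r = 30 µm.

### Chemistry

Each droplet runs an arbitrary reaction network with mass-action kinetics
evaluated on mol/L concentrations. A `Reaction` carries stoichiometric
counts (which determine how amounts change) and, optionally, separate
kinetic orders (for lumped reactions whose empirical rate law differs from
the stoichiometry) plus an optional catalyst whose concentration
multiplies the rate. Every reaction must balance monomer-equivalent mass
(Σ count·MW equal on both sides to 10⁻⁹ relative), so chemistry conserves
total solute mass exactly.

The default network is a condensation polymerization of a
glycylglycine-like monomer M (132 g/mol, exchangeable) into a chain-length-10
polymer P (1320 g/mol, trapped, osmotically active):

    10 M → P   rate k_init·[M]²      (initiation, k_init = 2·10⁻⁶ L·mol⁻¹·s⁻¹)
    10 M → P   rate k_auto·[M]·[P]   (autocatalytic growth, k_auto = 3.5·10⁻⁴ L·mol⁻¹·s⁻¹)

The design intent: condensation *reduces* particle count inside the
droplet, but the monomer deficit is refilled from the shared bath (fast,
because M is small) while the product stays trapped. A droplet that
polymerizes faster therefore ends up with *more* osmotic particles than
its neighbours and grows at their expense — chemical performance becomes
physical size. This only works when the monomer refill time τ is short
compared with the incubation; at r = 25 µm and the default k_s the refill
is too slow and fast polymerizers transiently *shrink* (their local
monomer depletion outweighs the trapped product). The default droplet
radius of 6 µm was chosen to put the platform in the regime where the
trapped-product advantage is net positive.

### Integration

Explicit Euler with operator splitting: chemistry is advanced within each
droplet, then the exchange fluxes are applied. The step length must
satisfy a stability bound of 10% of the fastest relevant relaxation, taken
over both channels: volume loss (dt ≤ 0.1·min V/(k_w·A·Π_max)) and solute
relaxation (dt ≤ 0.1·min (V/A)/coef for the fastest-permeating species).
`step` rejects a dt above the bound; `incubate` subdivides automatically,
so long runs never fail as gradients steepen. Amounts are clipped at zero
(clipped mass is logged cumulatively; zero in all default scenarios) and
droplets shrinking below the 0.5 µm extinction floor are removed and
logged rather than ever reaching negative volume. A droplet whose volume
did not change in a step keeps its radius bitwise, so a gradient-free
population is an exact fixed point.

Convergence was checked against dt/10 reference integrations (two-droplet
oracle, mixed-population trajectories agree within 1% at the default dt).

## The recursive platform

One generation is: **incubate → measure → sort → fuse → split → pool**.

* The trait z is the end-of-incubation diameter (µm); the alternative
  choices (growth rate, growth increment) would need only a different
  measurement at the same point in the cycle.
* Sorting: *individual* mode keeps droplets with D ≥ f (ties kept);
  *subpopulation* mode bins droplets into equal-width diameter bins
  (default 4) and keeps whole bins whose mean diameter passes f,
  emulating passive fractionation into groups.
* Each survivor is fused with one fresh feedstock droplet (same size
  distribution as generation 0, monomer-only composition) and then split
  once into two offspring. Fuse-then-split is the fixed order; volumes
  and amounts are additive under fusion and exactly conserved under
  splitting (bitwise: the two children's amounts sum to the parent's).
* Splitting partitions volume exactly as φ/(1−φ) (default 0.5), and each
  species with fraction φ·(1+η), η ~ N(0, partition_noise_sd²), clamped
  to keep both children non-negative. Partition noise (default 0.1) is
  the platform's source of heritable variation between siblings.
* The offspring pool is restored to n_droplets by uniform subsampling or
  fresh-feedstock top-up. Fitness w_i is the parent's realised offspring
  count in the returned population (0 for discarded droplets); an
  offspring that goes extinct before its own measurement is dropped from
  both the parent's w and its offspring-trait list, so fitness always
  means "offspring surviving to measurement".
* If no droplet passes the threshold, the next generation is founded from
  fresh feedstock with a logged warning; the population never empties.
* After the final generation one extra incubation measures the last
  offspring cohort, so every generation record carries a complete
  decomposition.

A single seeded `numpy` Generator is threaded through all stochastic
operations in a fixed order (initial generation; then per generation:
feedstock draws, partition noise, subsampling), making every run, and
every CSV it writes, reproducible from the top-level seed.

## Evolution metrics

Per generation the trait change decomposes by the Price identity

    w̄·Δz̄ = Cov(w, z) + E(w·Δz),

with population (÷n) moments, Δz_i the difference between the mean trait
of droplet i's offspring and its own trait (terms with w_i = 0 contribute
zero), and Δz̄ the fitness-weighted offspring mean minus the parent mean.
Computed this way the identity holds to rounding; the residual is
reported as a self-check (≲10⁻¹⁴ on fuzzed and simulated records). The
covariance is computed in centered form so uniform fitness yields an
exactly zero selection term. The per-generation environment change Δe is
reported alongside the transmission term as an annotation: no quantitative
form for folding it into the algebra is defined, and none is invented.

Polydispersity is s/d: the standard deviation of droplet radius over its
mean. The sample convention (n−1) is the documented default and is
configurable (`ddof`). A run is flagged *evolving* when the Kendall rank
correlation between generation index and the tracked series is positive
and the fraction of strictly increasing successive steps reaches a cutoff
(default 0.6).

## Imaging

`render_frame` rasterises a population as an 8-bit monolayer micrograph:
mid-grey background (128), a dark interface ring (32) drawn *inward* from
the true radius (width 2 px), interior slightly lighter than background
(140). Droplets are placed by greedy seeded dart throwing with a minimum
interface gap (6 px) and full-margin border clearance, so ground-truth
circles never touch the border; Gaussian pixel noise is added and clipped.

`detect_droplets` mirrors a real-time size readout: Gaussian smoothing →
global Otsu threshold (which isolates the dark ring class) → fill enclosed
regions → connected components → discard border-touching or sub-minimum
components → centroid + equivalent-circle radius √(area/π), sorted by
size. The default smoothing σ = 0.5 px is deliberately small: heavier
smoothing smears the minority ring class toward the background mode, which
drags the between-class-variance threshold upward and dilates the mask
(σ = 1 already biases radii by ~3–4%; σ = 0.5 keeps the mean absolute
radius error ≈ 0.1% at pixel-noise σ = 8). Because the ring is drawn
inward, the filled mask has the droplet's true area and
radius-from-area is essentially unbiased; an explicit circle fit (e.g.
Hough) is a documented alternative, not the default.

The renderer emulates contrast and noise, not optics: no defocus,
illumination gradients, occlusion or droplet contact deformation. Detector
benchmarks on these frames therefore bound performance on *clean,
non-overlapping* monolayers only; real micrographs would need the
parameters (σ, min_area) retuned and would likely require overlap
handling.

## Default parameters

| parameter | default | units | rationale |
|---|---|---|---|
| k_w | 0.01 | µm·L·mol⁻¹·s⁻¹ | mixed 50 mM scenario coarsens visibly within the 7500 s observation window |
| k_s | 0.001 | µm/s @ mw_ref | monomer refill fast at r = 6 µm (τ ≈ 2600 s), slow at r = 30 µm |
| mw_ref | 100 | g/mol | reference for the inverse-MW law |
| MW monomer / polymer | 132 / 1320 | g/mol | glycylglycine-like monomer; chain length 10 |
| k_init | 2·10⁻⁶ | L·mol⁻¹·s⁻¹ | seeds ~10⁻⁴ M polymer per incubation at 50 mM monomer |
| k_auto | 3.5·10⁻⁴ | L·mol⁻¹·s⁻¹ | per-incubation polymer gain e^(k_auto·[M]·T) ≈ 2.9, just above the 2× fusion/split dilution, so polymer compounds across all 10 generations instead of saturating early |
| init_radius (evolution) | 6 | µm | puts monomer refill inside the incubation window (see above) |
| init_radius (coarsening) | 30 | µm | monolayer-scale droplets for the imaging emulation |
| init_radius_cv | 0.02 | — | small seed variation; keeps trait noise below the polymer-driven signal |
| incubation_time (evolution) | 6·10⁴ | s | ≈ one autocatalytic e-folding; several monomer refill times |
| dt | 50 / 5 | s | ≤ 1/5 of the stability bound in each scenario |
| size_threshold_f | 12 | µm (diameter) | the monodisperse starting diameter: keeps roughly the upper half |
| split_fraction | 0.5 | — | symmetric division |
| partition_noise_sd | 0.1 | — | heritable composition variation between siblings |
| extinction floor | 0.5 | µm | removal radius; avoids negative volumes |

All of these are exposed in the YAML configuration; none is hard-coded in
the algorithms.

## What the synthetic experiments show — and what they don't

* The **coarsening emulation** (mixed 50 mM glycylglycine vs. pure water,
  monodisperse start, 7500 s) reproduces the qualitative phenomenon:
  strictly rising s/d, solute-class droplets growing (+1.26 µm mean
  radius) while water-class droplets shrink (−1.38 µm), and identically
  flat s/d for unmixed controls. The physical constants are not fitted to
  any measured trajectory, so agreement is qualitative by design.
* The **recursive-selection experiment** (10 generations × 100 droplets,
  default chemistry) shows a positive rank correlation of mean trait with
  generation for all of seeds 0–9 under the defaults, driven by heritable
  polymer accumulation; the neutral control (no chemistry, no size
  variation, no partition noise) is exactly flat. This demonstrates the
  platform's selection–heredity loop functioning in simulation; it says
  nothing about any particular laboratory chemistry.
* The **detector benchmark** (50 frames, ~50 droplets each, pixel noise
  σ = 8) achieves exact counts and ≈ 0.1% mean radius error on the
  renderer's own conventions; end-to-end s/d through render→detect agrees
  with the simulated radii within 0.5%.

## Numerical and degenerate-case policy

* Identical osmolarities/concentrations short-circuit to exactly zero
  fluxes (the area-weighted mean of a constant vector is taken as that
  constant), so null controls are bitwise static.
* Ties at the size threshold are kept. The bundled neutral-control
  scenario sets f one percent below the monodisperse diameter because a
  tie can be broken by one ulp of fuse/split round-off.
* Populations must be non-empty for any dynamics step; an empty detection
  list (blank frame) is a result, not an error; a frame with fewer than
  two detections records a missing s/d and the run continues.
* Kendall tau of a constant series is reported as 0 (no trend).

## Known limitations

* Mean-field exchange: no droplet positions, no local neighbourhoods, no
  contact-mediated transfer; an optional pairwise-neighbour topology is a
  possible extension, not implemented.
* No Laplace-pressure (curvature) term, surfactant film physics, or
  oil-phase solubility: coarsening here is purely osmotic.
* Explicit Euler: first-order accurate; the stability bound and dt/10
  convergence checks stand in for adaptivity.
* The imaging layer is a synthetic fixture; see above.
* Fitness is realised offspring count under a fixed 2-offspring scheme,
  so w̄ is pinned near 1 by population-size control; selection intensity
  is governed by the threshold, not by fecundity differences.
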