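# Model and methods

`spindlesim` simulates the earliest stage of mitotic spindle assembly in a
fission-yeast-like geometry, asking whether a passive antiparallel
microtubule (MT) crosslinker that locally stabilizes MT dynamics — the
Ase1/PRC1 + Cls1/CLASP module — is sufficient to build a bipolar spindle
with **no molecular motors at all**.  The method is a hybrid of overdamped
Brownian dynamics (BD) for the mechanical degrees of freedom and kinetic
Monte Carlo (kMC) for discrete state changes (crosslinker binding, MT
catastrophe/rescue).

## Geometry and mechanics

* The **nuclear envelope (NE)** is a fixed sphere (diameter 2.75 µm); it
  never changes shape.  Fission yeast mitosis is closed, so the whole
  simulation lives inside this sphere.
* The two **spindle pole bodies (SPBs)** are thin disks embedded in the NE,
  described by an outward unit normal and an in-plane angle.  They
  translate in the membrane (measured in-membrane diffusion coefficient
  `D_SPB = 4.5e-4 µm²/s`) and rotate in-plane diffusively.  Each carries a
  ring of 14 nucleation sites (ring radius half the SPB radius).  Forces on
  an SPB come from its own aster (transmitted through the MT pivots), from
  soft SPB–SPB exclusion, and from MT tips of the *other* pole pressing on
  its disk.  The collective translational drag of an SPB includes the
  slender-body drag of its attached aster, so a pole carrying long MTs
  moves more sluggishly.
* **Microtubules** are rigid rods pivoting about their nucleation site
  (pivot tether).  The orientation diffuses and responds to torques with
  the slender-body end-pivot drag
  `gamma = 4 pi eta L^3 / (3 (ln(L/d) + 0.84))`, viscosity
  `eta = 1 pN s/µm²` (~1 Pa·s nucleoplasm); rotational mobility is thus
  length-dependent, so freshly nucleated 0.1 µm stubs tumble in fractions
  of a second while 2 µm polymers are nearly frozen orientationally.
  Angular moves are capped at 0.3 rad per step for stability.
* MT–MT **steric repulsion** is a WCA-type capped soft repulsion
  (`epsilon = 1 kT`, cutoff `2^{1/6} d`, cap 10 pN) acting between segment
  closest points; coincident rods are separated along a deterministic
  perpendicular tie-break.  MTs also repel the opposite SPB disk (soft
  linear exclusion, 300 pN/µm): a plus end polymerizing into the opposite
  pole pushes the poles apart, the motor-free pole-separation mechanism.
* The **wall force** on a plus tip protruding a distance `L` past the NE
  models membrane-tube formation: the sum of the small-deformation linear
  response of a tensed membrane to a point load (slope fixed by the tube
  radius `R_tube` and Euler's constant `gamma = 0.5772...`, damped beyond
  the tension length `b = sqrt(2) R_tube`) and the tube regime
  `F_w (1 + a e^{-cL/b})` with `a = 0.5416`, `c = 4.038`, multiplied by a
  `1 - e^{-L}` blend (decay scale 10 R_tube by default, configurable) so
  that `F(0) = 0` exactly and `F -> F_w` within 1% by `L = 100 R_tube`.  The force acts radially inward at
  the plus tip only.  The reference set uses `F_w = 0` (free tube
  formation), the regime in which simulated spindles remain short.

## Dynamic instability

Plus ends switch between growth and shrinkage with the four-parameter
model: growth speed `v_g`, shrinking speed `v_s`, catastrophe frequency
`f_c`, rescue frequency `f_r`; switching is one Bernoulli draw per MT per
step with probability `1 - e^{-f dt}`.  The reference values
(`v_g = 0.04 µm/s`, `v_s = 0.15 µm/s`, `f_r = 0.05 /s`, and `f_c` derived)
are fixed by requiring the bounded-growth steady-state mean length
`v_g v_s / (f_c v_s - f_r v_g)` to equal 0.64 µm — short, rapidly
turning-over MTs whose constant re-exploration lets antiparallel contacts
form quickly.

A shrinking MT reaching the minimum length (0.1 µm) *renucleates*: it is
floored there, switched to growth, and its orientation is redrawn from the
nucleation template — the inward site normal plus a Gaussian tilt
(`nucleation_tilt_sigma = 0.3`).  This re-pointing is essential: without
it, orientations random-walk to isotropy and the asters lose their mutual
facing geometry.

Growth against a compressive axial tip load `F` (from the NE wall force or
from pressing on the opposite SPB disk) follows the shared-load
multi-filament Brownian ratchet for a 13-protofilament lattice, each
subunit advancing the tip by `sigma = 8/13 nm`:
`v(F) = v_g (alpha e^{-beta} - 1)/(alpha - 1)` with
`alpha = e^{F_s sigma / kT}`, `beta = F sigma / kT`; `v(0) = v_g`, strictly
decreasing, stalling at `F_s = 8 pN` (clamped at zero beyond stall rather
than depolymerizing).

**Crosslink-induced stabilization** models CLASP recruitment by the
crosslinker: whenever a doubly bound crosslinker head lies within the
stabilization length `s = 0.1 µm` of a plus end (arc distance along that
MT), that MT's parameters rescale toward stability —
`f_c / s_fc`, `f_r * s_fr`, `v_g * s_vg`, `v_s / s_vs` (reference factors
4, 20, 1.5, 8).  Factors saturate (multiple crosslinks do not stack).  The
stabilized reference parameters sit deep in the unbounded-growth regime,
so crosslinked overlap MTs elongate persistently while unlinked MTs keep
turning over.

## Crosslinkers

Crosslinkers have two heads and three states (free / one head bound / two
heads bound).  The kinetics are built to make *static* filaments relax to
the exact Gibbs distribution of the spring energy:

* free → one-bound at `k_on,1` per µm of MT lattice within the capture
  radius (= rest length, 53 nm); the landing point is uniform on the
  nearby lattice.  The reverse move repositions the freed crosslinker
  uniformly in the capture sphere around the released head — the detailed
  balance partner of the binding move, giving the one-bound/free weight
  ratio `k_on,1 V_capture / k_off,1` per unit lattice length.
* one-bound → two-bound with rate density
  `k_on,2 e^{E_b} e^{-k (r - r_0)^2 / 2kT}` along every *strictly
  antiparallel* partner MT (orientation dot product below −0.3); the total
  rate integrates this Boltzmann factor over the partner (the filament-pair
  partition function, 0.01 µm quadrature bins within the 12 kT energy
  window) and the landing position is drawn from the same density.
* unbinding at constant off-rates (a Bell slip-bond factor is available,
  default off).

At most one transition per crosslinker per kMC interval (first-order
splitting; rates × interval is kept small).  Doubly bound crosslinkers are
harmonic springs (`k = 207 pN/µm`, rest length 53 nm) exerting equal and
opposite forces and torques at their attachment points.  Bound heads
diffuse along the lattice (`D = 0.1 µm²/s`) with drift down the axial
spring force, integrated with an Ornstein–Uhlenbeck update (exact for a
linear force of stiffness `k`), which is unconditionally stable however
stiff the spring; free crosslinkers diffuse in the nucleoplasm
(`D = 1 µm²/s`), confined to the NE interior by rejection of
wall-crossing steps (which preserves the uniform stationary measure
exactly at any step size).  Crosslinkers do not sterically
interact with each other.

The first 0.1 µm of lattice at each minus end is excluded from binding
(`minus_end_exclusion`), representing occlusion by SPB material at the
nucleation site.  This matters structurally: without it, crosslinkers pile
into near-pivot junctions between diverging MTs and glue each aster into a
rigid ball instead of populating extended antiparallel overlaps.

## Bipolarity order parameter and success criterion

The **interpolar fraction (IF)** of a configuration is the fraction of MTs
currently engaged in at least one doubly bound crosslink with an MT of the
opposite pole (count-based definition; the classifier threshold is a
parameter so a recalibrated definition can be swapped in).  A run is a
successful bipolar spindle if the IF exceeds 0.2 from some crossing time
until the end of the simulation, for at least 2 minutes, tolerating
individual sub-threshold dips of up to 12 s (the duration clock is not
reset by a tolerated dip; a trailing dip within the allowance also
qualifies).  The formation start time is the first crossing of the
qualifying epoch; the late-time SPB separation averages the pole-pole
distance over the final 30 s.

## Reference parameter set and calibration

Lengths in µm, time in s, force in pN; `kT = 4.11e-3 pN µm` (the standard
~25 °C convention).  Values with direct experimental anchors (envelope and
SPB dimensions, MT diameter, 14 nucleation sites, SPB mobility, crosslinker
spring and rest length, 10-minute simulated window) are fixed at
fission-yeast-scale numbers.  The dynamic-instability set is pinned by the
0.64 µm mean-length calibration.  The remaining crosslinker kinetic
constants, the crosslinker count (600), the antiparallel selectivity
threshold (−0.3), the minus-end exclusion and the nucleation tilt have no
direct measurements; following the selection rule of preferring values
that give a high rate of bipolar assembly where measurements are missing,
they were calibrated in exploratory runs until the reference set assembled
spindles robustly (8/10 seeds) while the stabilization knockout never did
(0/10), and then frozen.  Every value is a config key, so a measured value can be
dropped in verbatim.

Sampling ranges for the 9-parameter random study default to one order of
magnitude either side of the reference dynamic-instability values, 0–2× the
reference crosslinker count, and 1–50 for the four stabilization factors;
a JSON ranges file overrides them.

## Numerics

* Operator splitting per step: deterministic forces → dynamic-instability
  switching and length update → crosslinker kMC and diffusion → Brownian
  moves.  The order is fixed and documented.
* Default timestep 5e-5 s.  Batch studies (scans, sweeps, the acceptance
  suite) use the documented *reduced-accuracy tier*: dt = 2 ms with
  crosslinker kinetics and diffusion sub-sampled every 20 steps
  (interval 40 ms).  At this tier single-run observables (assembly
  outcome, late separation) are statistically indistinguishable from
  dt = 0.5 ms runs in spot checks, but individual trajectories are not
  converged path-wise; the tier exists to make many-hundred-run studies
  practical on a workstation.
* Steric pairs use a centre-distance Verlet list rebuilt every 20 steps
  (0.05 µm skin).  SPB positions are integrated by an unconstrained
  tangent-plane step followed by radial reprojection (O(dt) weak error).
* Every run is bitwise reproducible from (resolved parameters, seed); scan
  replicates derive order-independent sub-seeds via `SeedSequence(master,
  spawn_key=(sample, replicate))`.
* Desk-scale study sizes used by the validation suite: 10 seeds for the
  reference/knockout comparison; 12 parameter sets × 3 replicates for each
  random-sampling study; 3–5 values × 3–5 replicates for the
  single-parameter trends; 500 MTs × 10⁴ s for the mean-length ensemble;
  10⁵ recorded samples for the frozen-pair equilibrium chain.  The
  full-scale studies (500 × 12 and 200 × 12 scans, 24 × 32 wall-force
  sweep) run unchanged through the same entry points on a cluster.

## What the synthetic conditions do and do not show

All inputs are generated: there are no experimental data files.  The
frozen-filament fixtures validate the crosslinker statistical mechanics
against direct Boltzmann integration; the single-MT ensembles validate the
dynamic-instability statistics against closed forms; the full engine is
validated against the qualitative biology (assembly with stabilization,
none without, crosslinker-number threshold, stabilization-factor
requirements).  Passing these tests shows the *mechanism* is sufficient in
the model's idealized geometry; it does not show quantitative agreement
with any particular cell, because kinetochores/chromosomes, motor
proteins, NE shape change, MT flexibility and crosslinker–crosslinker
sterics are all deliberately outside the model.

## Known limitations

* With zero wall force the spindles that form are short (≈0.2–0.8 µm
  late-time separation), at the low end of experimental metaphase lengths;
  raising the wall force in this implementation does **not** push the
  poles to opposite sides of the envelope, because protruding tips are
  spread nearly isotropically around each aster and their inward forces
  largely cancel instead of acting along a dominant interpolar bundle.
  The wall-force dependence of spindle *length* is therefore muted
  compared to the strong dependence reported for this class of models.
* The engine supports only the pivot interpretation of the minus-end
  tether (minus end pinned at its site).  The harmonic tether force law is
  implemented and tested on explicitly placed minus ends, but a free-rod
  integrator with tether springs is not wired into the stepping loop; the
  stiff spring would force a much smaller timestep for no observed change
  in behaviour at this scale.
* Heads that diffuse past a plus end are clamped at the tip (they detach
  only when the tip shrinks past them).  Clamped tip-heads transmit a
  small net overlap-contracting force; the SPB-disk exclusion opposes it.
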