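# Methods

`flexgel` simulates a coarse-grained mixture of crosslinked semiflexible
polymers whose bending rigidity can be switched off, and measures the volume
response of the network. The model isolates the mechanism proposed for
heat-induced shrinkage of printed collagen hydrogels: folded collagen
behaves as a stiff filament, heat-denatured collagen as a flexible coil, and
the permanent crosslinks written during printing survive the transition.
Switching a crosslinked mixture from stiff to flexible chains at constant
pressure is therefore a minimal computational analogue of heating a printed
gel through its unfolding transition.

## Model

Beads of mass m (one per monomer) interact through three terms:

* **Bonds and crosslinks** — harmonic springs
  `V_bond = K_bond (d − 2r)² / 2` with rest length `2r`, where `r` is the
  bead radius. Crosslinks use the same constant and rest length as chain
  bonds.
* **Steric repulsion** — the repulsive `r⁻¹²` term of a Lennard-Jones
  potential, `V_rep = 4ε(σ/d)¹²`, truncated at `d_cutoff` and energy-shifted
  so the energy is continuous at the cutoff (the force is untouched; the
  shift is a constant ≤ 4·10⁻³ ε for every cutoff the package uses).
  Repulsion is excluded for directly bonded pairs. The exclusion also
  covers crosslinked pairs: a crosslink is a bond with the same rest length,
  so both kinds of bonded pairs are treated identically.
* **Bending** — `V_angle = K_θ [cos θ − cos θ₀]² / 2` on every triad of
  consecutively bonded beads, with θ₀ = 180° (a straight chain is the
  minimum). The potential is *quartic*, not harmonic, around θ₀. Setting
  the flexible flag makes this term identically zero while leaving the
  topology untouched.

The bead radius is tied to the repulsion length by `r = σ·2^(1/6)/2`, so the
bond rest length `2r` is the distance at which two soft spheres touch.

Reduced units: lengths in σ, energies in k_BT, masses in bead masses. The
natural time unit is the bead diffusion time `τ = (2r)²/D` with
`D = k_BT/(mγ)`; the integration step is `Δt = 1.587·10⁻³ τ`, the value
implied by the protocol's step-count–to–τ conversions (6·10⁸ steps ↔
0.952·10⁶ τ), and the barostat coupling time is `τ_p = 0.07937 τ ≈ 50 Δt`.

### Dynamics

Langevin dynamics with friction mγ is integrated by the BAOAB splitting
(half kick, half drift, exact Ornstein–Uhlenbeck velocity refresh, half
drift, half kick), one force evaluation per step. The scheme reproduces
the Einstein relation `D = k_BT/(mγ)` for a free bead and equipartition
`⟨KE⟩ = k_BT/2` per degree of freedom to well under the test tolerances at
the default Δt; both are verified by the suite.

Thermal noise comes from a counter-style splitmix64 generator feeding a
128-layer ziggurat sampler, built into the integrator: exact
standard-normal sampling with an explicit 64-bit state, no allocation, and
bit-reproducible trajectories for a fixed seed. Seeds are scrambled through
the splitmix finalizer so that adjacent integer seeds give unrelated noise
streams. The suite checks the sampler's moments and tail mass against the
standard normal.

Pressure coupling is the Berendsen weak-coupling scheme: after each step the
box edge and all coordinates are rescaled by
`μ = [1 − κ(Δt/τ_p)(P₀ − P)]^(1/3)`, where `P = (N·k_BT + W/3)/V` is the
instantaneous virial pressure (W sums `f·d` over all pairwise interactions;
the three-body bending term contributes through its two vertex-relative
displacement vectors). μ is clamped to [0.99, 1.01] per step; clamped steps
are counted and logged. Berendsen dynamics relax the volume without
sampling a strict isothermal–isobaric ensemble — adequate here, where the
observables are time-averaged volumes of well-relaxed stages.

Distances use the minimum-image convention in a cubic periodic box
throughout. Neighbors are kept in a two-level Verlet buffer: an outer
"super" list with a generous skin rebuilt by an O(N²) scan only when a bead
has drifted more than half the super skin, and the force list refreshed
cheaply by filtering the super list (skin 0.4 σ, rebuild when a bead moved
more than half the skin, with a small margin for the ≤1% affine drift the
barostat may apply between rebuilds). O(N²) rebuilds are adequate at desk
scale (10²–10⁴ beads); list equivalence with a brute-force scan is tested.
A step that moves any bead farther than half the skin aborts the stage with
a stability error suggesting a smaller Δt.

## Protocol

1. **Initialization** — `n_chains` straight chains of `dp` beads at spacing
   2r, random positions and orientations, rejection-sampled so no two beads
   come closer than σ; thermal velocities at k_BT (this removes the kinetic
   equilibration transient, which matters for second-scale smoke runs).
2. **Compression** — the box edge is interpolated linearly to each target
   over a prescribed number of steps while dynamics runs, coordinates
   rescaled affinely each step; the final edge hits the target exactly.
3. **Self-assembly** — barostat-coupled dynamics; the volume trace is
   normalized by the close-packing volume `V_CP = 4√2 r³N` (equivalently
   `V_mon·N` divided by the close-packing fraction π/(3√2) ≈ 0.7405, the
   printed factor ≈1.35·V_mon·N). Snapshots are recorded for conformation
   selection.
4. **Conformation selection** — k snapshots whose volumes are spread evenly
   across the observed range, each target matched by the closest unused
   snapshot; the smallest-volume slot is by convention the final snapshot.
   Labels run 'a' (largest) to 'd' (final). Deterministic given the trace.
5. **Crosslinking** — every pair of beads on *different* chains closer than
   2r (minimum image) is linked independently with probability `P_CL`; a
   bead may carry several links (the literal Bernoulli rule). Eligible and
   realized counts are reported.
6. **Stiff / flexible stages** — barostat-coupled dynamics with the bending
   potential active, then zeroed; the crosslink list is immutable through
   both. The `P_CL = 0` control reuses the trailing `stage_steps` of the
   assembly as its stiff stage and runs a fresh bending-free continuation
   as its flexible stage.

The swelling factor is `S_V = ⟨V_flexible⟩/⟨V_stiff⟩`, time averages taken
over the trailing half of each stage and replicas pooled by concatenating
their trailing windows before averaging. The phase map tabulates S_V
against `⟨V_stiff⟩/V_CP` (same trailing window) and `P_CL`.

## Persistence length

For an isolated chain, bond tangents `t̂_i` give the mean correlation
`C(s) = ⟨t̂_i·t̂_(i+s)⟩`, fitted by log-linear least squares to
`C(s) = exp(−s·b/l_p)` (b = mean bond length). The fit range runs from
s = 0 while C(s) > 0.05, but never beyond about one persistence length
(estimated from the nearest-neighbor decay) and never beyond 13
separations, with a minimum of three. The l_p cap matters for flexible
chains: beyond ~l_p the decay of a self-avoiding chain is governed by
excluded-volume correlations that the worm-like-chain form does not
describe, and including that tail inflates the fitted l_p severalfold.
The hard cap matters for stiff chains: the statistical error of C(s) at
separation s is set by bending modes of wavelength ~s·b whose relaxation
time grows like s⁴, so a long fit range adds slowly-averaging noise much
faster than signal — for 50-bead chains it cuts the seed-to-seed spread of
the estimate several-fold at no cost in bias. Confidence intervals come from a moving-block
bootstrap over snapshots (blocks of ~1/50 of the ensemble), which tolerates
residual correlation between consecutive samples. A flat correlation
(perfectly straight ensemble) reports l_p at a configurable cap.

The bending constant for a target persistence length is calibrated through
an independent single-angle Boltzmann quadrature:
`⟨cos θ⟩(K_θ) = ∫ cos θ · e^(−V_angle/k_BT) sin θ dθ / ∫ e^(−V_angle/k_BT) sin θ dθ`,
solved for K_θ such that `−⟨cos θ⟩ = exp(−b/l_p)` (the sign reflects the
interior-angle convention: a straight chain has θ = 180°, so consecutive
tangents are aligned when cos θ = −1). Because V_angle is quartic at its
minimum, no closed harmonic form applies and the integral is evaluated by
adaptive quadrature. The quadrature ignores excluded volume (single-angle
factorization); the round-trip against simulation is part of the suite.
The stiff stage uses K_θ calibrated for l_p = 50 r (K_θ ≈ 414 k_BT); the
measured flexible-chain l_p is ≈ 2 r, so the stiffness switch spans a
~20-fold measured drop in persistence length for 50-bead chains.

## Parameters and defaults

| parameter | default | role |
|---|---|---|
| K_bond | 200 k_BT/σ² | bond/crosslink stiffness; keeps bond-length fluctuations (≈0.07 σ) ≪ σ at the default Δt |
| ε | 1 k_BT | repulsion strength (0.25 k_BT in the desk-scale presets: the contact-rich regime in which Bernoulli crosslinking of sub-2r contacts yields at least one link per chain at P_CL = 25%, i.e. a spanning network) |
| σ | 1 (unit) | repulsion length |
| d_cutoff | 2.5 σ | repulsion truncation (1.8 σ in the desk-scale presets, where the discarded tail is < 4·10⁻³ k_BT) |
| K_θ | 0 (presets: 414 k_BT) | bending constant; 0 = fully flexible |
| γ | 1 /t₀ | velocity relaxation rate (t₀ = σ√(m/k_BT)) |
| Δt | 1.587·10⁻³ τ | integration step (≈2.0·10⁻³ t₀) |
| p_target | 0.5 k_BT/σ³ | barostat target pressure |
| τ_p | 0.07937 τ | barostat coupling time (≈50 Δt) |
| κ | 1 σ³/k_BT | barostat compressibility factor, folded into the coupling strength |
| skin | 0.4 σ | neighbor-list buffer |

The interaction constants in physical units are not fixed by the
coarse-grained model itself, so ε, K_bond, d_cutoff, γ and the reduced-unit
value of the pressure target are package choices, made once and documented
here; every one is configurable.

## What the synthetic generator does and does not emulate

The generator reproduces the study conditions' geometry: random straight
chains, the two-step compression, densities preserved across presets by
scaling box edges with the cube root of the bead count (`full` is
200×50 beads in a (399.6 σ)³ box compressed to (48 σ)³ then (30 σ)³;
`demo` is 20×25 beads with the same initial and compressed densities).
It does not emulate collagen's triple-helix geometry, sequence-specific
interactions, solvent, electrostatics, or the topology change when a helix
separates into three chains; passing tests therefore support the abstract
stiffness-switch mechanism, not any quantitative statement about collagen.

Desk-scale caveats, measured during development and worth stating plainly:

* Chains longer than the box. Both the reference system (contour 55 σ,
  box 30 σ) and the scaled presets have chains longer than the compressed
  box, so each chain interacts with its own periodic images; the network is
  effectively an infinite entangled mesh rather than a droplet.
* Annealing time. The stiff chains order slowly (the rotational
  relaxation of a 25-bead rod is of order 4·10⁵ steps at the default
  friction, and the reference protocol annealed for 6·10⁸ steps). The
  presets' assembly stages leave an isotropic, jammed rod mesh whose
  pressure exceeds the flexible melt's at equal density, so the
  *uncrosslinked control also contracts slightly* upon flexibilization —
  the one piece of the reference phenomenology (control swelling) the
  desk-scale presets do not reproduce; the acceptance suite reports this
  honestly as a failing sub-property. The expectation from the mechanism
  is that the control swells once assembly has annealed the stiff mesh
  below the flexible phase's equilibrium volume, which requires far more
  assembly time than a minutes-scale preset affords.
* Contact statistics. Crosslink-eligible contacts (inter-chain pairs
  closer than 2r) are a small fraction of all pairs at these densities;
  the realized link count per chain, not P_CL itself, controls whether a
  spanning network forms at desk scale.

## Numerical choices

* Energy shift (not force shift) at the repulsion cutoff; dynamics are
  unaffected, recorded energies differ from the unshifted form by a
  constant.
* cos θ is clamped to [−1, 1] before the bending force evaluation to guard
  against roundoff at perfectly straight triads.
* Berendsen μ clamped to [0.99, 1.01]; pathological excursions (μ³ ≤ 0)
  clamp to the lower bound and log a warning.
* Conformer selection ties break toward the earliest snapshot; the final
  snapshot always fills the smallest-volume slot.
* Errors inside a compiled stage (instability, overlap, list overflow) are
  returned as status bits; the stage finishes cheaply on garbage data and
  the caller raises, discarding the result.
* Time-unit audits flag step/τ conversions that disagree by more than 1%.

## Known limitations

* Berendsen coupling does not sample the true NPT ensemble; volume
  fluctuations are suppressed relative to it.
* The O(N²) neighbor-list rebuild bounds practical system sizes to ~10⁴
  beads.
* The persistence-length estimator assumes a single exponential regime at
  short separations; for strongly swollen chains the reported l_p depends
  on the fitted range by construction, which is why the range is pinned to
  the initial decay.
* S_V for the scaled-down presets carries replicate spread of a few
  percent; single cells close to S_V = 1 can change side between seeds.
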