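# Methods

This note documents the model implemented in `cgfibril`, the choices made
where the design was genuinely open, and what the package's tests do and
do not demonstrate.

## The coarse-grained model

One D-glucose residue maps to four beads at the positions of its O2, O3,
C6 and O6 atoms.  Bead types are Martini 3: TC1 (tiny apolar) for the
C6-centred bead, SP6 (small polar) for the three oxygen-centred beads;
masses follow the Martini 3 size convention (tiny 36 amu, small 54 amu,
regular 72 amu); all charges are zero, so electrostatics is a no-op (a
config hook exists for charged extensions).

Intra-chain structure is maintained by a harmonic elastic network over
the triangulation of the chain ribbon: six intra-residue pairs, plus
O2-O2 / O3-O3 / C6-C6 pairs between first and second residue neighbours.
The pair list, spring lengths r₀ and constants k are tabulated in
`cgfibril.params.BONDED_PARAMS`; k is interpreted as kJ mol⁻¹ nm⁻² in
V = ½ k (r − r₀)², the conventional unit for elastic-network constants of
this magnitude (30 000; the two flexible pairs O2-O6 and O3-O6 use
2 500).  Bonds are harmonic, not rigid constraints: the model's distance
fluctuations are physical observables.  No angle or dihedral potentials
exist — the triangulation alone carries the ribbon geometry.

Nonbonded interactions are plain Lennard-Jones 12-6 with an exact
tabulated (σ, ε) per bead-type pair and **no combining rules**: looking
up a pair that is not tabulated is an error by design.  The LJ potential
is truncated and potential-shifted at 1.1 nm.  Pairs joined by an
elastic bond are excluded from LJ (stiff pairs sit far below σ and would
otherwise blow up); no deeper exclusions are applied.  The consequences
of this exclusion choice are discussed under *Known limitations*.

## Closed-form ideal geometry

The builder produces ideal chains from the published distances alone,
with no atomistic input:

1. The axial rise per residue is half the second-neighbour repeat,
   h = 10.44/2 = 5.22 Å.  Residue i is the image of residue 0 under a
   two-fold screw: translate i·h along z, rotate odd residues 180° about
   the z axis.  This makes every second-neighbour distance exactly
   10.44 Å.
2. The cylinder radius of O2, O3 and C6 about the screw axis follows
   from the first-neighbour distances: d₁² = 4r² + h².
3. O2 and C6 are placed in the y = 0 plane *on the same side* of the
   axis; O3 follows by triangulation against both, O6 by trilateration
   from the other three (positive branch).  The same-side placement is
   the unique member of the one-parameter embedding family for which the
   twist dihedral (O2ᵢ, C6ᵢ, C6ᵢ₊₁, O2ᵢ₊₁) is exactly 0° at every
   junction — the ideal chain is an untwisted flat ribbon.

All tabulated distances are reproduced to < 1e-9 Å; the builder's output
doubles as the zero-temperature reference for every distance statistic.

Fibrils replicate the chain on a two-dimensional lattice.  The packing
presets (in-sheet spacing 8.2–8.6 Å, sheet stacking 3.9–6.0 Å, c/4 axial
staggers, antiparallel checkerboard for type-II) are idealized: they
follow the symmetry classes of the three crystal forms but the spacings
are widened relative to the crystallographic unit cells so that beads of
adjacent chains keep ≥ 2 Å clearance (the 4-bead ribbon is wider than a
real glucan cross-section).  All presets are overridable via
`LatticeSpec`.

## Simulation engine

Internal units are nm / ps / amu / kJ mol⁻¹ (coordinates are Å at the
API surface).  Defaults mirror the production protocol the parameter set
was derived with: 0.02 ps timestep, 300 K, 1.1 nm cutoff.  Vacuum NVT
(or NVE) only: the structural observables validated here do not require
pressure coupling, and solvent beads are outside scope (the W cross
terms are stored but unused by default).

* **Thermostats.**  Default is BAOAB Langevin with friction 1 ps⁻¹; the
  stochastic velocity-rescaling (Bussi) thermostat is available.  All
  noise derives from one NumPy PCG64 generator seeded from the config;
  trajectories are bit-reproducible for a fixed seed, and the seed is
  recorded in the trajectory metadata.
* **Neighbour lists** are Verlet lists (KD-tree build, 0.3 nm skin)
  rebuilt when the maximum displacement exceeds half the skin; forces
  are evaluated in numba kernels.
* **Kinetic temperature** is reported from half-step-averaged velocities
  (the leapfrog convention).  At Δt = 0.02 ps the stiffest network modes
  sit at ωΔt ≈ 1.6, where on-step velocities under-report the kinetic
  temperature by ~10%; the half-step estimator recovers the target to
  < 1%.  The v-rescale thermostat controls the on-step estimate by
  construction.  Configurational averages (the quantities all distance
  statistics use) are unaffected by this choice.
* **Minimization** is steepest descent with an adaptive step and a
  max-force stopping criterion, monotone non-increasing by construction.
* **Degenerate inputs** (coincident beads, non-finite coordinates) are
  rejected before dynamics; instability during a run raises an error
  naming the step.

### Integration at the production timestep

The published elastic constants (30 000 kJ mol⁻¹ nm⁻²) with Martini
small/tiny masses put the stiffest normal modes of the network at
ωΔt ≈ 1.6 for Δt = 0.02 ps — inside but close to the velocity-Verlet
stability limit of 2.  Two measurable consequences, both properties of
the discretization and not of the force field:

* NVE total-energy drift of ~0.1–0.7% per 10⁵ steps (seed-dependent);
  at Δt = 0.01 ps the drift falls below 0.015%, confirming the
  integrator is symplectic and correctly implemented.  The test suite
  asserts conservation at 0.01 ps; thermostatted production runs absorb
  the residual drift.
* The on-step kinetic-temperature bias described above.

## Analysis

* **Pair distances** are pooled over all matching pairs, chains and
  frames; histograms use Freedman–Diaconis binning (overridable) and are
  density-normalised.
* **RMSD** uses Kabsch superposition (via
  `scipy.spatial.transform.Rotation.align_vectors`) by default; without
  superposition rigid-body diffusion of a vacuum system dominates and
  the statistic is meaningless for these runs.  Cross-RMSD evaluates
  every (optionally strided) frame pair between two trajectories and
  reports mean ± SD and the pair count.
* **Twist angle**: the signed dihedral over (O2ᵢ, C6ᵢ, C6ᵢ₊₁, O2ᵢ₊₁),
  atan2 convention with the reference quadruple
  (0,0,0),(1,0,0),(1,1,0),(1,1,1) scoring −90° (mdtraj's convention is
  the mirror of this one; tests pin the relation).  Statistics pool all
  junctions, chains and frames, matching the printed max/min magnitudes'
  implication of per-junction pooling.  The quadruple ordering is
  configurable.

## Parameter scan

The scan reproduces the selection protocol at reduced scale: a grid of
candidate Martini types for the oxygen beads (the C6 bead pinned to TC1,
overridable) × soft-spring constants {25, 250, 2500}, each scored by the
time-average superposed RMSD of short runs on each requested system.
"Simultaneously small for all fibrils" is operationalized as minimizing
the *maximum* per-system mean RMSD (mean aggregation available).
Unstable or parameter-less grid points are recorded and skipped, and
ranking a saved results table is pure.  Only the published (σ, ε) subset
ships with the package; scanning other types requires a user-supplied
parameter map, so the packaged scan demonstrates the machinery, not a
full re-derivation.

## What the synthetic systems do and do not show

The builder's ideal structures stand in for the atomistic reference
crystals, and all dynamics is vacuum dynamics of reduced systems (a
20-residue chain; 3×3-chain × 20-residue fibrils) rather than solvated
36-chain × 100-residue fibrils.  Consequences:

* Stiff-bond distance means recover their r₀ closely (eight of the nine
  k = 30 000 pair classes within 0.023 Å in a 5 ns single-chain run) — a
  property of the unfrustrated elastic network.  The one exception is
  the second-neighbour O3-O3 mean, which settles at 10.38 Å (r₀ 10.44)
  in vacuum: the same intra-chain LJ frustration that drives the
  spurious vacuum twist (below) compresses the O3 edge of the twisted
  ribbon.  The deviation is stable over 10 ns and unchanged at halved
  and quartered timesteps, i.e. it is the model's vacuum equilibrium,
  not an integration artifact.  Fluctuation widths (SDs) are smaller
  than in solvated systems and should not be read quantitatively.
* Time-average RMSD of the reduced systems stays bounded (≲ 5 Å),
  consistent with the model's structure-preserving design.
* The **twist behaviour of reduced vacuum systems is qualitatively
  wrong**: without solvent pressure and full-size packing, the
  non-excluded near-bonded LJ contacts of the ideal ribbon
  (C6ᵢ–O3ᵢ₊₁ at 4.21 Å against σ = 4.84 Å, O6ᵢ–O2ᵢ₊₂ at 4.31 Å) exert a
  chiral torque that the soft O2-O6/O3-O6 springs cannot balance, and
  chains relax into a strongly right-handed state (tens of degrees per
  junction, versus ~±1° for the full solvated systems).  Because all
  three allomorphs share the same chain chirality, reduced fibrils of
  every allomorph twist with the same sign: the allomorph-specific twist
  signs (type-II left-handed, I-forms right-handed) are *not*
  reproduced at desk scale.  Excluding LJ to bond-graph depth 2 removes
  the torque but leaves a lone chain torsionally floppy (twist SD ≈ 40°,
  time-average RMSD ≈ 6.7 Å); with the published parameter set there is
  no exclusion depth that reproduces both the small RMSD and the twist
  signs in vacuum at this system size.  The bonded-pair exclusion
  (depth 1) is retained as the default.

## Known limitations

* No barostat, no explicit solvent, no reaction-field electrostatics
  (all charges are zero); W-W self-interaction is not tabulated and
  vacuum is the default medium.
* The lattice presets are idealized packings, not refined unit cells;
  results that depend on absolute interchain distances should treat them
  as adjustable.
* Harmonic springs cannot represent the bimodality of the O2-O6 and
  O3-O6 distance distributions geometrically; it is represented
  dynamically by the soft 2 500 kJ mol⁻¹ nm⁻² constants.
* XTC reading requires a model for the topology; multi-frame GRO is the
  native trajectory format (0.001 nm file precision).
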