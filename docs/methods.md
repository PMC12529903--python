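# Model and methods

`polyqcg` implements a two-bead-per-residue implicit-solvent coarse-grained
model of polyglutamine (polyQ) aggregation, together with the simulation
protocols and analyses needed to study β-sheet formation, steric-zipper
packing, and seeded amyloid growth.  This note documents the model, every
tunable parameter, the numerical choices, what the synthetic fixtures do
and do not represent, and the known limitations.

## Representation

Each glutamine residue carries two massive beads: a backbone bead (BB, at
the Cα position, 56 Da) and a side-chain bead (SC, 72 Da).  One extra BB
bead caps each terminus so that every residue has backbone neighbours on
both sides; a polyQ_n chain therefore has n+2 BB and n SC beads.  Three
virtual (massless) interaction centres per residue are deterministic
functions of the BB positions:

* **HBO** (acceptor, oxygen-like) at 1/3 of the forward backbone bond,
  offset perpendicular by l_HB = 0.238 nm along the local backbone normal
  n̂ (the normalised cross product of consecutive bond vectors);
* **HBH** (donor, hydrogen-like) at 2/3 of the backward bond, offset by
  −l_HB along n̂;
* **Ref**, the midpoint of the two flanking BB beads, a bonded-geometry
  anchor that takes part in no nonbonded interaction.

The 1/3 vs 2/3 placement makes the two faces of a strand inequivalent,
which is what renders antiparallel β-sheets more stable than parallel
ones in this model (the package's sheet builder demonstrates this: both
donor/acceptor families can be brought into exact registry only in the
antiparallel arrangement).

Forces on virtual sites are transferred to their BB parents through the
exact Jacobian of the construction, including the derivative of the
normalised cross product; after projection, virtual beads carry zero
force and the analytic forces match central-difference gradients of the
total energy to better than 1e-4 kJ/mol/nm (tested).

## Interactions

* **Bonds.**  Harmonic, k = 8038 kJ/mol/nm²; BB–BB at l_BB = 0.38 nm,
  SC–BB at l_SC = 0.424 nm.
* **Side-chain restraint.**  Harmonic angle SC–BB–Ref with equilibrium
  180° and k = 1000 kJ/mol/rad², keeping the side chain on the outward
  bisector of the local backbone.
* **Nonbonded (BB/SC).**  A shifted 8–6 Lennard-Jones potential: a soft
  ε_rep = 10 kJ/mol repulsive core of diameter σ = 0.476 nm whose outer
  branch is (ε_rep − ε_ij)(σ/r)⁸.  The pair strength follows the
  combination rule ε_ij = ε_hp (λ_i λ_j)^α with ε_hp = 13 kJ/mol,
  α = 0.27, λ_BB = 0.64, λ_SC = 0.58.  Pairs are net attractive only when
  ε_ij > ε_rep, i.e. λ_i λ_j > (10/13)^(1/α) ≈ 0.379; with the calibrated
  defaults BB–BB is marginally attractive and SC–SC marginally repulsive,
  placing the default model near the boundary between dispersed and
  phase-separated states (raising λ_SC to ≈ 0.63 crosses the attraction
  threshold).  Cutoff 2.4σ ≈ 1.14 nm with per-pair energy shift to zero;
  exclusions cover bead pairs within two bonds (1–2 and 1–3, including a
  side chain with its own and adjacent backbone beads).
* **Hydrogen bonds.**  HBO–HBH pairs only (never HBO–HBO or HBH–HBH)
  interact through ε_HB [q¹² − 2q⁶] with q = σ_HB/(r+σ_HB), σ_HB = 0.42
  nm, ε_HB = 6.6 kJ/mol, multiplied by the quintic switch
  S(x) = 1 − 10x³ + 15x⁴ − 6x⁵, x = r/σ_HB, so the potential is exactly
  zero at and beyond r = σ_HB and an ideal bond (r = 0) has energy
  −ε_HB.  Same-residue and adjacent-residue pairs of one chain are
  excluded to suppress self-bonding artifacts of the virtual
  construction.

## Stand-in backbone potentials

The residue-specific bending, torsion and bend–torsion coupling
potentials of the parent one-bead-per-residue force field are obtained by
Boltzmann inversion of Ramachandran statistics and are not
redistributable here.  The package exposes a pluggable interface
(`BackbonePotentials`; tabulated two-column files are accepted) and ships
a **non-calibrated stand-in**: a harmonic bend at 127° (the β-region
pseudo-bond angle; the ideal-strand geometry used by every fixture
builder follows from it) with k = 150 kJ/mol/rad², a weak single-cosine
torsion (k = 2 kJ/mol, trans minimum), and no coupling term.

Two considerations fixed the bend stiffness.  Below ≈100 kJ/mol/rad² the
backbone occasionally straightens completely; at a straight backbone the
Ref anchor coincides with its BB bead and the 180° side-chain restraint
becomes singular, which destabilises dynamics at the default 0.02 ps
step.  Substantially stiffer values make short chains rod-like.  150
kJ/mol/rad² keeps the restraint safe while leaving chains flexible on the
10-residue scale.

**Consequences of the stand-in (important).**  Single-chain statistics
are close to, but stiffer than, the calibrated model: the apparent R_g
scaling exponent measured at desk scale comes out above the published
0.52.  More significantly, the amyloid core's thermal metastability at
300 K is *not* reproduced: an ideal β-sheet bond is worth only
ε_HB = 2.65 k_BT in a potential whose minimum sits at zero separation
(vanishing 3-D phase space), so per-bond binding free energy is marginal
and the calibrated backbone's strong β-basin is what tips the balance in
the parent model.  With the stand-in, sheets are stable at 150 K but
melt at 300 K within ~0.1 ns, and stacked sheets additionally drift
apart because inter-sheet side-chain contacts are net-neutral/repulsive
at the default λ values.  The package therefore measures the intersheet
spacing — a packing quantity calibrated against the 8.2 Å experimental
value — on the **energy-minimised** stack (steepest descent to its
mechanical packing optimum), where it is well defined and reproduces
8.2 Å at l_SC = 0.424 nm and increases monotonically with l_SC.  Tests
that probe thermal metastability of preformed seeds at 300 K are
included and fail under the stand-in; they document the gap rather than
hide it.

## Dynamics

Langevin leapfrog ("sd"-style): full-step force kick, Ornstein–Uhlenbeck
velocity update with decay exp(−dt/τ) and matched Maxwellian noise,
position drift.  Defaults follow the published protocol: 300 K,
dt = 0.02 ps, inverse friction τ = γ⁻¹ = 2 ps.  Only massive beads are
integrated; virtual sites are re-placed inside every force evaluation.
A velocity-Verlet NVE mode exists for energy-conservation checks (drift
< 1e-3 kJ/mol per bead over 10⁴ steps at dt = 0.002 ps).  At the default
0.02 ps step the measured kinetic temperature of dense systems runs a
few percent above the target — ordinary leapfrog discretisation error
for the stiffest modes (bond period ≈ 19 steps).

Neighbor lists are Verlet lists over periodic k-d trees (cutoff + 0.2 nm
skin, rebuild when any tracked bead moves half the skin); a brute-force
all-pairs oracle in the test suite pins their correctness.  Energy
minimisation is steepest descent with an adaptive step.

## Protocols

* `run_protocol` — equilibration with hydrogen bonds disabled, then
  production with them enabled, mirroring the published two-phase
  protocol (500 ns + 5 μs at full scale; desk-scale runs use the same
  structure at ns durations).
* `phase_sweep` — one independent, individually seeded cell per
  (λ_SC, ε_HB) combination; the default grid is λ_SC 0.48–0.68 in steps
  of 0.05 × ε_HB 4.6–10.6 in steps of 1.0 kJ/mol (35 cells).  Per-cell
  outputs: cluster count, hydrogen bonds per molecule, zipper fraction.
* `seeded_growth_protocol` — a preformed stack centred in a box whose
  volume sets the monomer concentration (default 1.0 mM); the run pauses
  every replenishment interval (100 ns at full scale), measures the
  largest cluster, and inserts monomers ≥ 1 nm from any bead to restore
  the dilute-phase count.  Inserted monomers are extended chains with
  random orientation.

## Analyses

* **Clustering** — molecules are connected when any of their BB or SC
  beads are within 0.6 nm (minimum image); clusters are connected
  components.  A cell-list/k-d-tree index accelerates the search; the
  all-pairs oracle defines correctness.
* **Hydrogen bonds** — HBO–HBH contacts within 0.12 nm, intra- and
  intermolecular, normalised per molecule; each residue is capped at two
  bonds (one per site).
* **Steric zipper** — for each candidate residue pair (same-chain pairs
  closer than three residues excluded), the four BB/SC bead distances
  are computed; a pair is in zipper conformation when the minimum lies in
  [0.38, 0.5] nm and the maximum in [1.2, 2.5] nm.  The default takes
  min/max over all four combinations; a mixed-kind-only mode is provided.
* **R_g** — mass-weighted over BB+SC beads after bond-walk unwrapping
  across the periodic boundary; a residual bond > 0.6 nm is treated as a
  broken frame.  The scaling exponent is the least-squares slope of
  log R_g vs log N.
* **Intersheet spacing** — total-least-squares planes are fitted to each
  sheet's BB beads; sheet centroids are projected onto the mean normal
  and adjacent gaps averaged.  Sheets come from builder metadata or, for
  simulation output, from connected components of the molecule graph
  with ≥ 2 shared intermolecular hydrogen bonds.

## Fixtures (what they emulate, what they do not)

Builders produce ideal geometries: planar zigzag strands at the bend
equilibrium; β-sheets with exact hydrogen-bond registry (coincident
HBO/HBH sites, backbones 2·l_HB = 0.476 nm apart); amyloid stacks with
sheets offset by half the strand spacing so side chains interdigitate
(steric zipper), default spacing 0.82 nm; and random solutions packed by
rejection sampling (0.5 nm clash cutoff, bounded retries) at a target
molarity.  The 4 × 4 antiparallel Q23 stack is the standard seed
fixture.  These are idealised starting structures, not equilibrium
ensembles: they contain no β-turn/β-arc motifs, no registry defects, and
single straight strands per sheet.  Passing tests on them validates
geometry, energetics and bookkeeping — not the spontaneous emergence of
amyloid order, which requires the calibrated backbone potentials and
μs-scale sampling.

## Scale of shipped computations

Desk-scale defaults keep the test suite and the reproduction script
within minutes on one CPU: the spacing fixture is 4 sheets × 6 strands
of Q16 (24 chains); seeded-growth checks use the 4 × 4 Q23 seed with
tens of monomers over ≤ 0.2 ns; scaling fits use Q16–Q48 with ns-scale
sampling.  Full-scale studies (100 × Q48 at 1.0 mM for 5 μs; 10 μs
seeded growth) run through the same drivers with larger arguments.

## Known limitations

* The stand-in backbone potentials are not the calibrated ones; all
  consequences above apply.  Calibrated tables, if available, can be
  supplied via `BackbonePotentials` without code changes.
* No electrostatics, explicit solvent, or many-body solvation effects;
  hydrophobicity is pairwise.
* NVT only (fixed cubic box); no pressure coupling or replica exchange.
* Thermodynamic stability of large aggregates at 300 K is outside the
  stand-in's reach (see above); kinetic studies of aggregation with this
  package should treat aggregate lifetimes as model-specific.
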