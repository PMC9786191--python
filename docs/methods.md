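# Methods

`poremcm` models how a small cationic blocker interacts with the pore domain
of a four-repeat P-loop channel (the hNav1.5 cardiac sodium channel is the
reference architecture) using Monte-Carlo minimization (MCM): random
perturbation of internal coordinates, local gradient minimization, and
Metropolis acceptance. This note records the model, its assumptions, the
defaults that matter, and what the synthetic test systems do and do not
show.

## Residue nomenclature

Pore-domain residues are named with universal P-loop labels
`<repeat><segment><relative position>`, segments `k` (S4–S5 linker), `o`
(S5), `p` (P-loop, numbered relative to the selectivity-filter position
p50) and `i` (S6). Mapping to UniProt numbers is affine per
(repeat, segment) and driven by a small anchor table; the packaged hNav1.5
table is compiled from published segment boundaries and the text anchors
F1760 = 4i15, M1652 = 4o1, M273 = 1o29, with the DEKA filter residues
(D372/E898/K1419/A1711) anchoring p50. The S5 anchors of repeats II and III
are not fixed by any in-text equivalence; the packaged values assume the
repeat-IV linker length (12 residues). Users can supply their own anchor
CSV (`channel,repeat,segment,anchor_relpos,anchor_resnum`). Voltage-sensor
residues carry no label and are referred to by plain numbers.

## Energy model

A reduced united-atom nonbonded model, deliberately not a reproduction of
any published force field:

* Lennard-Jones 12-6 with a ~10-entry type table (`rmin/2`, `eps`),
  Lorentz–Berthelot-style combination (`rmin` additive, `eps` geometric);
* Coulomb electrostatics with the distance-dependent dielectric
  `eps(r) = eps0*r` (default `eps0 = 4`), i.e. pair energies fall off as
  `1/r^2`;
* a 9 Å cutoff with a shifting function that takes the energy *and* its
  first derivative exactly to zero at the cutoff; pairs involving an atom
  of an ionized group (ammonium nitrogen, carboxylate oxygen) are computed
  with no cutoff at all;
* 1-2 and 1-3 bonded pairs excluded, 1-4 scaled by 0.5 (conventional);
* optional harmonic bonds, used by the synthetic channels to keep segments
  coherent while protocols drag them.

Consequences: absolute kcal/mol values are model-internal. Signs,
orderings, cutoff behaviour and brute-force equivalence are the meaningful
outputs, and those are what the tests assert. Hydrogen bonding is implicit
in the charges; there is no solvation, entropy, or periodic boundary
treatment. Real-structure (PDB) energy evaluation requires an explicit
bond list for the exclusion rules; the package does not infer covalent
connectivity of arbitrary proteins, so experimental structures are used
for geometric analyses (widths, censuses, superpositions) rather than
energies.

## Restraints

* **Pin**: flat-bottom parabola on a Cα position — zero within 1 Å of the
  template, `10 kcal mol⁻¹ Å⁻²` beyond. Preserves the fold during all
  protocols.
* **Plane**: holds an atom in a plane normal to the pore axis. Enforced by
  projection after each random move plus a stiff harmonic
  (`1000 kcal mol⁻¹ Å⁻²`) during minimization; post-step violation is
  within 0.05 Å.
* **Axial distance**: holds the ligand's para-carbon at a target
  cylindrical radius about the pore axis, leaving azimuth and height free
  (equivalently, a sphere of fixed radius whose centre slides along the
  axis). Same projection + stiff-harmonic enforcement.

## MCM engine

State = channel Cartesian coordinates (with a designated mobile-atom set
for the pulling protocols), channel side-chain torsions (a chi1-like
rotation about CA→CB), and ligand rigid-body pose + rotatable torsions.
The local minimizer is L-BFGS-B with analytic gradients; Cartesian forces
are chained through the rigid-body Jacobian (left Jacobian of the SO(3)
exponential map for the orientation block) and the standard torsion-axis
formula. A trajectory terminates when `patience` consecutive minimizations
fail to improve the apparent global minimum (production default 1000;
per-step pulling defaults 200/100). Metropolis temperature `kT = 0.6`
kcal/mol (conventional; configurable). An optional per-DOF trust bound on
the minimizer (`minimizer_bound`) turns a minimization into a local
relaxation; the protocols use it where a smooth coarse landscape would
otherwise let a relaxation slide across basins that in a rugged all-atom
landscape would trap it.

Low-energy ligand poses are clustered into a stack: records within
7 kcal/mol of the best, at most 100 records, two records merged when their
ligand heavy-atom RMSD (common frame, no superposition) is below 1.5 Å,
keeping the lower-energy representative. The thresholds are explicit
parameters.

## Docking

Random starts (mass centre uniform in an 8 Å sphere at the focus of the P1
helices — computed as the least-squares closest point of the four P1 axes,
which lies in the central cavity — orientations uniform over rotations,
torsions uniform), a fixed count of coarse MC-minimizations per start, full
MCM refinement of the energetically best complexes, all results merged into
one stack. Ranking between stages uses total system energy; reported pose
tables are filtered by the ligand-channel *interaction* energy within a
10 kcal/mol window, annotated with contact residues (heavy atoms within
4 Å, labelled through the annotations) and classified geometrically: ring
centroid beyond 8 Å from the pore axis = fenestration-reaching
(tonic-block-like, "TB"), else inner-pore ("UDB"). Production start counts
are hundreds; the test and acceptance runs use 25–40 starts with shortened
refinement, which is sufficient on the toy systems' small search volume.

## Voltage-sensor deactivation

The five S4 gating-charge Cα atoms of one repeat are pulled down the pore
axis through successive sets of planes (default 21 × 0.5 Å = 10.5 Å
total). Per step, pulled atoms move freely in their planes, every other
Cα of the mobile region is pinned to the *starting* structure, and the
energy is MC-minimized; each step chains from the previous minimized
structure. The mobile region is the union of a 12 Å neighbourhood of the
commanded pull path and everything within 16 bonds of the pulled atoms
(the drag chain S4 → linker → contacted helices). Deactivating all four
sensors in sequence (order I, II, III, IV) yields a resting-state-like
model; omitting repeat III leaves its sensor activated. Tests run the same
10.5 Å displacement in 7 × 1.5 Å steps with small per-step patience — a
desk-scale choice that preserves the commanded displacement and the
direction of the structural response.

## Ligand egress

From a bound state, the para-carbon's distance from the pore axis is
stepped outward (default 80 × 0.4 Å = 32 Å). Each step runs a constrained
MCM (stage 1, channel backbone fixed) and then removes the constraint for
a trust-bounded local relaxation (stage 2); the recorded point is the
relaxed state and the next step chains from it. The commanded radius
ladder is anchored at the starting radius, so a step that relaxes backward
does not stall the scan; achieved radii are recorded alongside targets,
and a ligand escaping beyond 1.5× the final radius truncates the profile
with a flag. The reported energy is the ligand-channel interaction energy.
Stage 2 as a bounded relaxation (rather than a free MCM) is a deliberate
deviation: smooth coarse landscapes cannot localize an unrestrained search
the way rugged all-atom ones do.

Profile analysis: interior minima are steps strictly below both neighbours
(plateaus count once, at their first step); the barrier between two points
is the highest energy on the path minus the energy at the origin. The
"barrier for leaving the bound site" takes the lowest point within 2.5 Å
of the starting radius as the bound-site energy (the chained scan may keep
relaxing during the first steps) and the deepest interior minimum at least
4 Å further out (or the profile end) as the exit target.

## Synthetic channels and ligands

The generator builds a coarse bead model of a four-repeat pore domain:
S5/P-loop/S6 segments per repeat around the z axis (extracellular up), a
5-bead S4 stub and an S4–S5 linker arc per repeat, a ring of
carbonyl-like charges (−0.45 e) at the p48 positions forming the
cation-attractive site at the outer-pore bottom, and one electronegative
interim-site attractor (−0.9 e) just outside each repeat interface.
Fenestration windows between adjacent S6 helices are lined by four bulky
aromatic-like side-chain beads; the planted width parameter *is* the
Cβ–Cβ distance across the window (the same measurement used for
experimental structures), adjusted purely through side-chain protrusion so
the backbone is identical at all widths. Bonded "curtain" and "wall"
lattices stand in for the packed protein that surrounds a real
fenestration, making the window the only lateral exit. Inter-repeat
contact bonds (linker→next-repeat S6, S4→next-repeat S5, S5→own S6) carry
the deactivation motion: pulling S4 of repeat r down drags S5 of repeat
r+1 down and toward repeat r, squeezing that S6 and narrowing the
r/(r+1) window — the same contact pathway proposed for the real channel.

Ligands: `mex_like` (ammonium bead, short linker, six-carbon aromatic ring
with a named para-carbon, net +1 e) and `thio_like` (longer
sulfur-containing linker, hence a larger amine-to-ring distance). The ring
flip is registered as a topological symmetry so pose RMSDs can be
symmetry-corrected.

`plant_pocket` surrounds a supplied collision-free pose with deep-well
beads (one per ligand atom where geometrically valid, mildly
electronegative, strongly so opposite the ammonium) so that the pose
becomes the global optimum of the docking search volume — the ground truth
for parameter-recovery tests.

What the toys do **not** emulate: side-chain rotamers (toy residues are
one or two beads), sequence realism, explicit S1–S3 voltage-sensor
helices, lipids and water, and absolute energetics. Passing tests
therefore demonstrate that the *protocols* behave correctly and that the
expected state-dependence *orderings* emerge from the assumed geometry and
interactions — not that the model predicts quantitative energetics of any
real channel.

## Study conditions reproduced as orderings

On synthetic channels at widths 9.0 / 9.5 / 12.0 Å (egress: 32 × 0.4 Å
steps, per-step patience 5; bound state constructed at the III/IV window
with the head at the carbonyl site):

* the bound-pose interaction energy is more favourable the wider the
  fenestration (activated-sensor-like state binds better);
* the barrier for leaving the bound site falls monotonically as the
  window widens;
* both narrow and wide profiles show an interior minimum at an
  intermediate radius — an interim site on the way to the lipids, created
  by the interface attractor.

These mirror, as orderings, the state dependence reported for
tonic block by local-anesthetic-like drugs: activation of the third
voltage sensor widens the III/IV fenestration, deepens the blocker's bound
state and lowers its access/egress barrier.

## Numerical choices and degenerate inputs

* Coordinates in Å; pore axis +z extracellular after alignment; residue
  numbering 1-based.
* Superposition is a Kabsch SVD fit with a determinant correction
  (proper rotations only); fewer than 3 paired atoms is an error.
* Alternate conformers: highest occupancy wins, ties broken by altloc
  identifier. Solvent dropped on reading by default.
* Quaternions kept unit-norm; torsions wrapped to (−π, π].
* A non-finite energy during minimization raises an error naming the
  closest atom pair.
* Stack updates reject non-finite energies; a record worse than
  best + window is dropped before clustering.

## Known limitations

* The channel backbone is rigid during docking and egress (only the
  pulling protocols move it); ligand bond angles are fixed, torsions free.
* Side-chain flexibility is a single chi1-like rotation; toy residues
  have none.
* The dielectric's environment dependence is not modelled — only the
  distance-dependent part, with `eps0` exposed.
* Interface censuses depend on explicit geometric thresholds
  (facing angle 60°, azimuthal wedge half-width 50°); on experimental
  structures these are calibration knobs, not ground truth.
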