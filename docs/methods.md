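# Methods

This note documents the models, numerical choices and known limitations of
`tunneldock`. It describes what the code computes; every number quoted here
is produced by the test suite or by `scripts/acceptance.py`.

## Rigid-body docking model

The workflow models a protein–ligand complex without any structural
relaxation: only translations and rotations are applied to rigid
experimental (or synthetic) conformers. Given a set of *templates* —
ligand copies already placed in the protein frame — and a *library* of
conformers of the same chemical species, the ensemble is the set of
least-squares superpositions of every conformer onto every template, in two
atom correspondences:

- **direct** — atom *i* of the conformer is paired with atom *i* of the
  template;
- **inverted** — atom *i* is paired with its end-to-end inversion partner,
  given by a per-species involutive permutation that exchanges the two
  molecular ends (hydroxyl oxygen ↔ hydroxyl oxygen, ring skeleton ↔ ring
  skeleton, polyene backbone reversed). This reproduces "docking the
  molecule the other way round" while keeping chemically analogous atoms
  paired. The permutation ships in a chemical-dictionary JSON file; for
  lutein it pairs the unprimed (β-end) atoms with primed (ε-end) atoms.

Superposition uses the Kabsch algorithm: SVD of the cross-covariance of the
centred point sets, with the standard sign correction (the axis of the
smallest singular value is flipped when the determinant would be −1), so
reflections are never returned. Fits are rejected as degenerate when either
centred point set has a relative second singular value below 1e-8
(coincident or collinear atoms).

## Scoring

Scores are deliberately simple, heavy-atom, distance-only criteria — the
regime appropriate for a coarse rigid-body search where structural
adjustment is anticipated but not modelled:

- **clash**: a (ligand heavy atom, protein heavy atom) pair strictly closer
  than 3.0 Å. Counted per pair by default; a per-atom mode (count ligand
  atoms with ≥ 1 close contact) is available since printed absolute clash
  counts can depend on this convention.
- **potential hydrogen bond**: a ligand hydroxyl oxygen within the closed
  window [2.0, 4.2] Å of a protein donor or acceptor atom (fixed residue
  table: backbone amide N donor except proline, carbonyl O acceptor,
  side chains per canonical chemistry, water O both). No angle term; the
  window is generous by stereochemical standards, by design.

Both thresholds are configuration-exposed with these defaults. Waters and
crystallization additives (HOH, EDO, SO4, TLA) are excluded from the scoring
atom set by default because the docked ligand occupies the cavity the
solvent fills; a flag re-includes them.

Two implementations are maintained: a k-d-tree neighbor query and an
exhaustive all-pairs enumeration. They are required to agree exactly
(integer equality) and this is asserted in the test suite and re-verified by
the acceptance script on every run.

## Classification and frequency analysis

Portals are flat gate planes (point + outward unit normal), either derived
from portal-lining residue selections (centroid; normal away from the cavity
centroid) or emitted analytically by the synthetic generator. A portal is
*penetrated* when at least one ligand heavy atom has positive signed
distance along the outward normal (threshold configurable). Poses divide
into two-portals / one-portal (portal 1 only) / portal-2-only / none. Ring
orientation compares the ε-ring centroid's distances to the two gate
points; ties break toward ε-in and the convention is logged in the class.

The orientation analysis restricts to the one-portal set with at least one
potential hydrogen bond, then takes the top decile by clash score. Because
clash scores are integers, the decile needs a tie convention: the cutoff is
the smallest integer *c* such that at least 10% of the set scores fewer
than *c* clashes, and all poses below *c* are included (the group can
exceed 10%). The two orientation counts are tested against equal expected
frequencies with a chi-squared goodness-of-fit (df = 1, no continuity
correction — counts are large, and applying none matches the analysis this
models). The fold ratio is reported at one decimal; full precision is kept
internally. With a zero denominator the fold is reported infinite and the
statistic is still computed.

The robustness battery re-scores the *same* pose set against perturbed
protein models — alternate-conformation choices, group deletion,
side-chain truncation to alanine — reporting each variant's summary and the
mean clash shift against baseline. Deleting atoms can only remove clashes,
which the tests assert pose-by-pose.

## Cavity detection

A regular voxel grid (default spacing 0.5 Å) is labelled protein / bulk /
cavity:

1. voxels within vdW + probe (probe 1.4 Å, water; Bondi radii table shipped
   as JSON) of any heavy atom are protein;
2. free voxels whose clearance from the protein surface admits a larger
   *bulk probe* (default 4.5 Å) are flood-filled from the grid boundary;
   the flooded region, dilated back by (bulk − small) probe within the free
   space, is bulk;
3. the remaining free voxels are cavity, in connected components sorted by
   size. Components smaller than one probe sphere are reassigned to bulk (a
   void a water cannot occupy is not a cavity).

The two-probe construction is what makes a *tunnel* reportable as a cavity:
openings narrower than the bulk probe are treated as sealed, while the
protein surface itself is still defined by the small probe. Cavity volume
is voxel count × spacing³; for a hollow sphere of accessible radius 6.2 Å
the measured volume is within ~1% of the analytic 998 Å³ at 0.5 Å spacing
(the acceptance tolerance is 10%).

Tunnel length is the shortest through-cavity path between the two
portal-adjacent voxel patches (or the extreme voxels along the cavity's
principal axis when no portals are given): Dijkstra on the Euclidean-
weighted 26-connected voxel graph, followed by taut-string straightening
(greedy line-of-sight shortcuts that stay inside the cavity). The
straightening matters: raw lattice geodesics overestimate lengths by up to
~7%, outside the intended ±1 voxel tolerance.

Enclosed solvent is counted by testing each solvent molecule's
representative point (water O; centroid for multi-atom additives) for
membership in cavity voxels.

## Synthetic study systems

The generator builds the scale model the analysis is designed around: a
tunnel ~20 Å long with free radius 3.5 Å and two unequal portals (aperture
radii 2.5 Å and 1.2 Å), and rigid two-ring diol ligands with 30.5 Å between
hydroxyl oxygens — so a docked ligand *must* protrude, which the tests
assert as a property. All dimensions are interior (solvent-accessible)
sizes; wall carbons sit 3.1 Å (C vdW + water probe) outside them.

- **Ligand**: a circular-arc backbone (chord 30.5 Å, sagitta 1.5 Å — the
  gentle bow seen in protein-bound carotenoids), 18 backbone carbons, a
  six-membered ring near each end (radii 2.0 Å "β" and 1.0 Å "ε"), one
  hydroxyl oxygen capping each end. Conformers are the canonical geometry
  plus isotropic Gaussian jitter (σ = 0.2 Å default, emulating
  conformational spread across crystal structures; the ring-size margin
  forbids σ ≥ 0.5 Å where labels would become ambiguous). Mean hydroxyl
  span over a 40-conformer library reproduces the target within ±0.2 Å.
- **Asymmetry**: the deep 5 Å of the default tunnel narrow to a 1.6 Å
  pocket. The ε ring (radius 1.0 Å) fits; the β ring (2.0 Å) cannot
  approach the pocket wall without many < 3 Å contacts. This plants a known
  ground truth: ε-ring-deep poses score far fewer clashes.
- **Polar sites**: two oxygens on the tunnel axis, one 3.2 Å beyond the
  deep gate and one 14.8 Å beyond portal 1 — i.e. 3.4–4.0 Å from where the
  deep and the protruding hydroxyls of a docked 30.5 Å ligand sit. That
  places them inside the hydrogen-bond window but outside clash range of
  both ring sizes, for both orientations. This placement was chosen
  deliberately: polar atoms nearer the portal rims interact with the rings
  orientation-dependently and would bias the *symmetric* control, which
  must show no preference.
- **Templates**: the paper-style manually positioned templates are replaced
  by a deterministic generator — the canonical ligand placed at evenly
  spaced depths near the deep gate (default 4 depths spanning
  [−0.6, +0.8] Å around it, the deepest crossing into the two-portal
  class) and evenly spaced rolls about the axis (default 3).
- **Null condition**: `TunnelSpec.symmetric()` removes the pocket and
  equalizes the portals; everything else is identical. Orientation counts
  then differ only through conformer jitter.

Default problem size is 4 × 3 templates × 40 conformers × 2 orientations =
960 poses per run, which keeps a 20-seed recovery experiment comfortably
inside a test session while leaving the chi-squared test massively powered
on the planted signal (p ~ 1e-58).

What the synthetic systems do **not** emulate: real side-chain chemistry and
rotamers, irregular (non-planar) portal shapes, solvent-mediated contacts,
conformer libraries with realistic torsional correlations, and crystal-
lattice artifacts. Passing the recovery tests therefore demonstrates that
the *pipeline arithmetic and geometry* are sound — that a planted steric
asymmetry of realistic scale is detected and a symmetric control is not
misreported — not that any particular real protein binds its ligand in a
given orientation.

## Numerical conventions

- Clash comparison is strict (<); the hydrogen-bond window is closed on
  both edges. Boundary examples are unit-tested.
- Winner selection: minimal clashes, ties by more hydrogen bonds, then
  lexicographic pose id.
- Pose order is lexicographic (template, conformer, orientation);
  regeneration from a spec + seed is bit-exact, asserted on coordinate
  bytes.
- Altloc handling: occupancy ties collapse toward altloc 'A'; chosen
  conformers are retagged altloc '' with occupancy 1.
- All randomness flows through numpy `default_rng` seeded from explicit
  spec fields; the acceptance script derives sub-seeds from `--seed` via
  `SeedSequence`.

## Known limitations

- Distance-only scoring cannot rank poses that differ mainly in hydrogen-
  bond geometry (no angles) or in contact severity (a 2.9 Å graze counts
  like a 1 Å interpenetration).
- Gate planes are flat; real portals are irregular, so portal classes near
  the plane are convention-dependent (the atom-count threshold is
  config-exposed).
- Chi-squared treats poses as independent, but poses sharing a conformer or
  template are correlated; with strong planted signals this is immaterial,
  and the symmetric control verifies the null behaviour under the default
  generator, but p-values on marginal real-data signals should be read
  cautiously.
- Cavity metrics depend on spacing, probe radii and the vdW table; they are
  calibration-grade (±10% against analytic solids), not exact.
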