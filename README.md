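# tunneldock

Rigid-body ensemble docking of elongated diol ligands into tunnel-cavity
proteins, with steric-clash / hydrogen-bond scoring and a chi-squared test
for binding-orientation preference.

## The problem

START-domain (helix-grip) proteins enclose a large (~1000 Å³) tunnel-like
cavity, about 20 Å end to end, that communicates with solvent through two
unequal portals. Xanthophyll carotenoids such as lutein are ~30.5 Å between
their terminal hydroxyl oxygens — too long to fit inside — so at least one
ionone ring must protrude through a portal. Because lutein is end-to-end
asymmetric (one β-ionone ring, one ε-ionone ring), a shape-asymmetric cavity
can, in principle, prefer one binding orientation and thereby discriminate
lutein from its symmetric relatives zeaxanthin and *meso*-zeaxanthin.

`tunneldock` implements the rigid-body modelling workflow used to test this
idea, end to end and fully runnable offline:

1. **structures** — PDB/mmCIF I/O (via `gemmi`), crystallographic altloc /
   occupancy models, ligand-conformer extraction with ring and hydroxyl
   annotations, donor/acceptor role assignment.
2. **superpose** — Kabsch least-squares superposition (proper rotations
   only), including the end-to-end *inverted* atom correspondence that docks
   a conformer in the flipped orientation.
3. **ensemble** — every library conformer × every docked template × both
   orientations → a provenance-tagged rigid pose set.
4. **scoring** — per pose: clashes (ligand–protein heavy-atom pairs < 3 Å)
   and potential hydrogen bonds (hydroxyl O to donor/acceptor, 2.0–4.2 Å),
   with a k-d-tree fast path that must agree exactly with an all-pairs
   oracle.
5. **classify** — portal penetration (gate-plane tests: one portal / two
   portals / none) and ring orientation (ε-ring toward the deep portal or
   not).
6. **orientation_stats** — the frequency analysis: restrict to the
   one-portal set with ≥ 1 hydrogen bond, take the top decile by clash
   score (integer cutoff, ties all-in), and compare the two orientation
   counts against a 50/50 expectation,

   χ² = (n_ε − n/2)²/(n/2) + (n_β − n/2)²/(n/2),  df = 1,

   plus robustness re-runs under protein-model perturbations (alternate
   conformations, loop deletion, side-chain truncation to alanine).
7. **cavity** — grid/probe cavity detection (two-probe flood fill), cavity
   volume, through-tunnel geodesic length, enclosed-solvent counting.
8. **synthetic** — parameterized tunnel proteins and rigid two-ring diol
   conformer libraries with *known ground truth*, so every stage is testable
   without downloading any structure.

## Worked example

```python
from tunneldock import run_synthetic_analysis

result = run_synthetic_analysis(seed=1)
s = result["summary"]
print(f"poses: {len(result['pose_set'])}")
print(f"analysis set (one portal, >=1 H-bond): {s.n_filtered}")
print(f"top decile: clash cutoff {s.clash_cutoff}, {s.n_top} poses")
print(f"orientation counts: {s.n_epsilon_in} epsilon-in vs {s.n_beta_in} beta-in")
print(f"chi2 = {s.chi2:.1f}, p = {s.p_value:.2e}")
w = result["winner"]
print(f"winner: {w.pose_id}, {w.clashes} clashes, {w.hbonds} H-bonds")
```

prints

```
poses: 960
analysis set (one portal, >=1 H-bond): 522
top decile: clash cutoff 1, 258 poses
orientation counts: 258 epsilon-in vs 0 beta-in
chi2 = 258.0, p = 4.68e-58
winner: t003_c016_direct, 0 clashes, 2 H-bonds
```

The default synthetic tunnel carries a narrow pocket at its deep end that
admits only the small (ε-analog) ring, so the planted preference is
ε-ring-deep; the pipeline recovers it decisively, and the winning pose
realises one hydrogen bond per hydroxyl — one inside the deep portal, one
outside the large portal. On the symmetric control tunnel
(`TunnelSpec.symmetric()`) the same analysis returns p ≈ 1.

The same stages are scriptable from the shell:

```bash
tunneldock synth tunnel --out tunnel.pdb
tunneldock cavity tunnel.pdb
tunneldock run --seed 1 --out run1/
tunneldock stats run1/scores.tsv
```

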