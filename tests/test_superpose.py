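"""Kabsch superposition, C-alpha RMSD and inverted correspondences."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from tunneldock.structures import Atom, LigandConformer, ProteinStructure
from tunneldock.superpose import (
    Correspondence,
    DegenerateGeometryError,
    RigidTransform,
    ca_rmsd,
    direct_correspondence,
    inverted_correspondence,
    kabsch_fit,
)


def _cloud(rng, n=10, scale=5.0):
    return rng.normal(0, scale, (n, 3))


class TestRigidTransform:
    def test_rejects_improper_rotation(self):
        M = np.diag([1.0, 1.0, -1.0])
        with pytest.raises(ValueError):
            RigidTransform(rotation=M, translation=np.zeros(3))

    def test_json_roundtrip(self):
        R = Rotation.from_euler("xyz", [0.3, -0.2, 1.1]).as_matrix()
        t = RigidTransform(rotation=R, translation=[1, 2, 3])
        back = RigidTransform.from_json(t.to_json())
        assert np.allclose(back.rotation, t.rotation)
        assert np.allclose(back.translation, t.translation)

    def test_compose_matches_sequential_application(self):
        rng = np.random.default_rng(0)
        a = RigidTransform(Rotation.random(random_state=1).as_matrix(), rng.normal(size=3))
        b = RigidTransform(Rotation.random(random_state=2).as_matrix(), rng.normal(size=3))
        pts = _cloud(rng)
        assert np.allclose(a.compose(b).apply(pts), a.apply(b.apply(pts)))


class TestKabschFit:
    def test_identity_on_identical_sets(self):
        pts = _cloud(np.random.default_rng(1))
        tf, rmsd = kabsch_fit(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(tf.rotation, np.eye(3), atol=1e-12)
        assert np.allclose(tf.translation, 0, atol=1e-12)

    def test_pure_translation_recovered(self):
        pts = _cloud(np.random.default_rng(2))
        tf, rmsd = kabsch_fit(pts, pts + [5.0, 0.0, 0.0])
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(tf.rotation, np.eye(3), atol=1e-10)
        assert np.allclose(tf.translation, [5, 0, 0], atol=1e-10)

    def test_matches_independent_lsq_rotation_oracle(self):
        # scipy's align_vectors solves the same weighted least-squares
        # rotation problem by an independent implementation
        rng = np.random.default_rng(3)
        pts = _cloud(rng)
        R_true = Rotation.random(random_state=4)
        target = R_true.apply(pts) + [1.0, -2.0, 0.5] + rng.normal(0, 0.1, pts.shape)
        tf, rmsd = kabsch_fit(pts, target)

        mov_c = pts - pts.mean(axis=0)
        tgt_c = target - target.mean(axis=0)
        R_oracle, _ = Rotation.align_vectors(tgt_c, mov_c)
        oracle_rmsd = float(
            np.sqrt(np.mean(np.sum((R_oracle.apply(mov_c) - tgt_c) ** 2, axis=1)))
        )
        assert np.allclose(tf.rotation, R_oracle.as_matrix(), atol=1e-6)
        assert rmsd == pytest.approx(oracle_rmsd, abs=1e-9)
        assert rmsd < 0.2  # noise scale

    def test_optimality_against_sampled_rotations(self):
        # no sampled proper rotation does better than the closed-form fit
        rng = np.random.default_rng(5)
        pts = _cloud(rng, n=4)
        target = Rotation.random(random_state=6).apply(pts) + rng.normal(0, 0.3, pts.shape)
        tf, rmsd = kabsch_fit(pts, target)
        tgt_c = target - target.mean(axis=0)
        mov_c = pts - pts.mean(axis=0)
        for trial in Rotation.random(2000, random_state=7):
            trial_rmsd = np.sqrt(np.mean(np.sum((trial.apply(mov_c) - tgt_c) ** 2, axis=1)))
            assert trial_rmsd >= rmsd - 1e-9

    def test_reflection_excluded(self):
        rng = np.random.default_rng(8)
        pts = _cloud(rng)
        mirrored = pts * [1, 1, -1]
        tf, rmsd = kabsch_fit(pts, mirrored)
        assert np.linalg.det(tf.rotation) == pytest.approx(1.0, abs=1e-9)
        assert rmsd > 0.5  # a proper rotation cannot undo a reflection

    @pytest.mark.parametrize(
        "bad",
        [
            np.zeros((4, 3)),  # coincident
            np.outer(np.arange(4.0), [1.0, 2.0, 0.5]),  # collinear
        ],
        ids=["coincident", "collinear"],
    )
    def test_degenerate_point_sets_rejected(self, bad):
        good = _cloud(np.random.default_rng(9), n=4)
        with pytest.raises(DegenerateGeometryError):
            kabsch_fit(bad, good)
        with pytest.raises(DegenerateGeometryError):
            kabsch_fit(good, bad)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_rmsd_invariant_under_common_rigid_pretransform(self, seed):
        rng = np.random.default_rng(seed)
        mov = _cloud(rng)
        tgt = _cloud(rng)
        _, rmsd = kabsch_fit(mov, tgt)
        R = Rotation.random(random_state=seed).as_matrix()
        t = rng.uniform(-10, 10, 3)
        _, rmsd2 = kabsch_fit(mov @ R.T + t, tgt @ R.T + t)
        assert rmsd2 == pytest.approx(rmsd, abs=1e-8)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_fitted_rmsd_never_exceeds_unfitted(self, seed):
        rng = np.random.default_rng(seed)
        mov = _cloud(rng)
        tgt = _cloud(rng)
        _, fitted = kabsch_fit(mov, tgt)
        unfitted = float(np.sqrt(np.mean(np.sum((mov - tgt) ** 2, axis=1))))
        assert fitted <= unfitted + 1e-9


class TestCorrespondence:
    def test_duplicate_indices_rejected(self):
        with pytest.raises(ValueError):
            Correspondence(pairs=[(0, 0), (0, 1), (2, 2)])

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            Correspondence(pairs=[(0, 0), (1, 1)])

    def test_inverted_correspondence_is_involutive(self, canonical_ligand):
        corr = inverted_correspondence(canonical_ligand)
        assert corr.label == "inverted"
        mapping = dict(map(tuple, corr.pairs))
        for i, j in corr.pairs:
            assert mapping[j] == i  # applying twice recovers direct pairing

    def test_inverted_selffit_swaps_headgroups(self, canonical_ligand):
        conf = canonical_ligand
        corr = inverted_correspondence(conf)
        tf, rmsd = kabsch_fit(conf.coords, conf.coords, corr)
        assert rmsd > 0.1  # asymmetric ends: the flip is not exact
        placed = tf.apply(conf.coords)
        i_beta, i_eps = conf.hydroxyl_indices
        # beta hydroxyl lands near the epsilon hydroxyl's original site
        assert np.linalg.norm(placed[i_beta] - conf.coords[i_eps]) < 2.0
        assert np.linalg.norm(placed[i_beta] - conf.coords[i_beta]) > 20.0

    def test_symmetric_toy_inverts_exactly(self):
        # mirror-symmetric 6-atom two-ring toy: inverted self-fit is exact
        half = np.array([[0.0, 0.0, 0.0], [1.0, 1.0, 1.0], [1.0, -1.0, 2.0]])
        # other end = image under a 180-degree rotation about the y axis
        # through (0, 0, 5), so the inverted correspondence is an exact symmetry
        coords = np.concatenate([half, (half * [-1, 1, -1] + [0, 0, 10])[::-1]])
        atoms = [
            Atom(serial=i + 1, name=f"C{i}", element="C", residue_name="TOY",
                 chain_id="L", residue_seq=1, position=c)
            for i, c in enumerate(coords)
        ]
        atoms[0].name, atoms[0].element = "O1", "O"
        atoms[5].name, atoms[5].element = "O2", "O"
        conf = LigandConformer(
            atoms=atoms,
            hydroxyl_indices=(0, 5),
            ring_labels={"beta": [1, 2], "epsilon": [3, 4]},
            inversion_map=np.array([5, 4, 3, 2, 1, 0]),
            species="TOY",
        )
        _, rmsd = kabsch_fit(conf.coords, conf.coords, inverted_correspondence(conf))
        assert rmsd == pytest.approx(0.0, abs=1e-9)


class TestCaRmsd:
    def _protein(self, coords, id="p"):
        atoms = [
            Atom(serial=i + 1, name="CA", element="C", residue_name="ALA",
                 chain_id="A", residue_seq=i + 1, position=c)
            for i, c in enumerate(coords)
        ]
        return ProteinStructure(atoms, id=id)

    def test_self_comparison_is_zero(self):
        s = self._protein(_cloud(np.random.default_rng(10), n=20))
        rmsd, n = ca_rmsd(s, s)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        assert n == 20

    def test_rigid_copy_is_zero(self):
        coords = _cloud(np.random.default_rng(11), n=20)
        R = Rotation.random(random_state=12).as_matrix()
        a = self._protein(coords)
        b = self._protein(coords @ R.T + [3, 4, 5], id="q")
        rmsd, n = ca_rmsd(a, b)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        assert n == 20

    def test_reports_pair_count_for_partial_overlap(self):
        coords = _cloud(np.random.default_rng(13), n=20)
        a = self._protein(coords)
        b = self._protein(coords[:15], id="q")
        _, n = ca_rmsd(a, b)
        assert n == 15

    def test_no_shared_residues_errors(self):
        a = self._protein(_cloud(np.random.default_rng(14), n=5))
        b_atoms = [
            Atom(serial=1, name="CA", element="C", residue_name="ALA",
                 chain_id="B", residue_seq=1, position=np.zeros(3))
        ]
        b = ProteinStructure(b_atoms, id="q")
        with pytest.raises(Exception, match="C-alpha"):
            ca_rmsd(a, b)
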