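"""Geometry: Kabsch superposition, RMSD/COM features, classification, PCA."""

import numpy as np
import pytest

from h12msm import (
    AtomSelection,
    FeatureSpec,
    ReferenceEnsemble,
    classify_by_reference,
    compute_com_distance_series,
    compute_rmsd_series,
    featurize,
    kabsch_superpose,
    make_swinging_helix_trajectory,
    pca_heavy_atoms,
)
from h12msm.trajectory import CoordinateTrajectory
from h12msm.generate import _helix_template, _random_rotation


def quaternion_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Independent oracle: Horn's quaternion method for the minimized RMSD."""
    A = mobile - mobile.mean(axis=0)
    B = reference - reference.mean(axis=0)
    M = A.T @ B
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    K = np.array(
        [
            [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
            [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
            [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
            [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
        ]
    )
    lam = np.linalg.eigvalsh(K)[-1]
    n = A.shape[0]
    sq = max(0.0, (np.sum(A**2) + np.sum(B**2) - 2 * lam) / n)
    return float(np.sqrt(sq))


def _traj_from(frames, atoms):
    return CoordinateTrajectory(xyz=np.asarray(frames), atoms=atoms)


@pytest.fixture
def helix_atoms():
    body, arm, atoms = _helix_template()
    return np.vstack([body, arm]), atoms


class TestKabsch:
    def test_identity_gives_zero_rmsd(self, helix_atoms):
        coords, _ = helix_atoms
        R, t, rmsd = kabsch_superpose(coords, coords)
        assert rmsd < 1e-12
        np.testing.assert_allclose(R, np.eye(3), atol=1e-9)

    def test_rigid_motion_invariance_and_proper_rotation(self, helix_atoms):
        coords, _ = helix_atoms
        rng = np.random.default_rng(3)
        for _ in range(5):
            Q = _random_rotation(rng)
            moved = coords @ Q.T + rng.normal(0, 10, 3)
            R, t, rmsd = kabsch_superpose(moved, coords)
            assert rmsd < 1e-9
            assert abs(np.linalg.det(R) - 1.0) < 1e-9
            np.testing.assert_allclose(moved @ R.T + t, coords, atol=1e-8)

    def test_reflection_related_inputs_stay_proper(self):
        rng = np.random.default_rng(5)
        A = rng.normal(size=(10, 3))
        B = A.copy()
        B[:, 0] = -B[:, 0]  # mirror image
        R, _, _ = kabsch_superpose(A, B)
        assert abs(np.linalg.det(R) - 1.0) < 1e-9

    def test_matches_quaternion_oracle_on_random_pairs(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            A = rng.normal(size=(10, 3))
            B = rng.normal(size=(10, 3))
            _, _, rmsd = kabsch_superpose(A, B)
            assert abs(rmsd - quaternion_rmsd(A, B)) < 1e-9

    def test_degenerate_selection_rejected(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError, match="collinear"):
            kabsch_superpose(line, line)


class TestRMSDSeries:
    def test_copies_of_reference_give_zero(self, helix_atoms):
        coords, atoms = helix_atoms
        traj = _traj_from([coords] * 4, atoms)
        np.testing.assert_allclose(
            compute_rmsd_series(traj, coords), 0.0, atol=1e-12
        )

    def test_single_displaced_atom_bound_and_oracle(self, helix_atoms):
        coords, atoms = helix_atoms
        delta = 0.5
        moved = coords.copy()
        moved[4, 2] += delta
        traj = _traj_from([moved], atoms)
        n = coords.shape[0]
        rmsd = compute_rmsd_series(traj, coords)[0]
        assert rmsd <= delta / np.sqrt(n) + 1e-9
        assert abs(rmsd - quaternion_rmsd(moved, coords)) < 1e-9

    def test_invariant_under_global_rigid_motion(self, helix_atoms):
        coords, atoms = helix_atoms
        rng = np.random.default_rng(11)
        frames = [coords + rng.normal(0, 0.3, coords.shape) for _ in range(3)]
        traj = _traj_from(frames, atoms)
        base = compute_rmsd_series(traj, coords)
        Q = _random_rotation(rng)
        moved = _traj_from([f @ Q.T + [3.0, -2.0, 7.0] for f in frames], atoms)
        np.testing.assert_allclose(
            compute_rmsd_series(moved, coords), base, atol=1e-9
        )


class TestCOMDistance:
    def test_pythagorean_pair(self):
        atoms = __import__("pandas").DataFrame(
            {"name": ["A", "B"], "resid": [1, 2], "resname": ["X", "X"],
             "element": ["C", "C"], "is_ca": [True, True], "is_heavy": [True, True]}
        )
        traj = CoordinateTrajectory(
            xyz=np.array([[[0.0, 0, 0], [3.0, 4.0, 0]]]), atoms=atoms
        )
        d = compute_com_distance_series(
            traj, AtomSelection(indices=np.array([0])),
            AtomSelection(indices=np.array([1])),
        )
        assert d[0] == pytest.approx(5.0, abs=1e-12)

    def test_coincident_groups_and_translation_invariance(self, helix_atoms):
        coords, atoms = helix_atoms
        g = AtomSelection(indices=np.arange(5))
        traj = _traj_from([coords, coords + 11.0], atoms)
        same = compute_com_distance_series(traj, g, g)
        np.testing.assert_allclose(same, 0.0, atol=1e-12)
        a = AtomSelection(indices=np.arange(5))
        b = AtomSelection(indices=np.arange(20, 31))
        d = compute_com_distance_series(traj, a, b)
        assert d[0] == pytest.approx(d[1], abs=1e-9)


class TestFeaturize:
    def test_columns_match_component_operations(self, helix_atoms):
        coords, atoms = helix_atoms
        traj = make_swinging_helix_trajectory(
            swing_angles=np.linspace(0, 2.0, 5), noise_sd=0.05, seed=2
        )
        sel = AtomSelection(indices=np.arange(traj.n_atoms))
        a = AtomSelection(indices=np.arange(20, 31), label="arm")
        b = AtomSelection(indices=np.array([0]), label="anchor")
        spec = FeatureSpec(rmsd_selection=sel, com_group_a=a, com_group_b=b)
        feats = featurize(traj, traj.xyz[0], spec)
        np.testing.assert_array_equal(
            feats.values[:, 0], compute_rmsd_series(traj, traj.xyz[0], sel)
        )
        np.testing.assert_array_equal(
            feats.values[:, 1], compute_com_distance_series(traj, a, b)
        )
        assert feats.feature_names == ("rmsd", "distance")

    def test_frame_zero_equal_to_reference(self, helix_atoms):
        coords, atoms = helix_atoms
        traj = _traj_from([coords], atoms)
        a = AtomSelection(indices=np.arange(20, 31))
        b = AtomSelection(indices=np.array([0]))
        spec = FeatureSpec(
            rmsd_selection=AtomSelection(indices=np.arange(31)),
            com_group_a=a, com_group_b=b,
        )
        feats = featurize(traj, coords, spec)
        assert feats.values[0, 0] == pytest.approx(0.0, abs=1e-12)
        assert feats.values[0, 1] == pytest.approx(
            compute_com_distance_series(traj, a, b)[0]
        )

    def test_empty_trajectory_gives_empty_features(self, helix_atoms):
        coords, atoms = helix_atoms
        traj = CoordinateTrajectory(xyz=np.empty((0, 31, 3)), atoms=atoms)
        spec = FeatureSpec(
            rmsd_selection=AtomSelection(indices=np.arange(31)),
            com_group_a=AtomSelection(indices=np.array([0])),
            com_group_b=AtomSelection(indices=np.array([1])),
        )
        feats = featurize(traj, coords, spec)
        assert feats.n_frames == 0


class TestClassifyByReference:
    def test_pure_and_planted_mixture_fractions(self, helix_atoms):
        coords, atoms = helix_atoms
        refA = coords
        refB = coords + np.array([0.0, 0.0, 30.0]) * 0  # same shape, build B below
        refB = coords.copy()
        refB[20:, :] = refB[20:, :] @ np.array(
            [[0.0, -1.0, 0], [1.0, 0.0, 0], [0, 0, 1.0]]
        ).T  # arm swung 90 degrees: large internal difference
        frames = [refA] * 3 + [refB] * 7
        traj = _traj_from(frames, atoms)
        panel = ReferenceEnsemble(
            references={"A": refA, "B": refB},
            selection=AtomSelection(indices=np.arange(31)),
            cutoff=0.5,
        )
        pops = classify_by_reference(traj, panel)
        assert pops["A"] == pytest.approx(0.3)
        assert pops["B"] == pytest.approx(0.7)
        assert pops["unassigned"] == 0.0
        assert sum(pops.values()) == pytest.approx(1.0, abs=0)

    def test_tight_cutoff_sends_all_to_unassigned(self, helix_atoms):
        coords, atoms = helix_atoms
        rng = np.random.default_rng(1)
        traj = _traj_from([coords + rng.normal(0, 1.0, coords.shape)], atoms)
        panel = ReferenceEnsemble(
            references={"A": coords}, cutoff=1e-6,
            selection=AtomSelection(indices=np.arange(31)),
        )
        pops = classify_by_reference(traj, panel)
        assert pops["unassigned"] == 1.0


class TestHeavyAtomPCA:
    def test_rank_one_motion_concentrates_variance(self, helix_atoms):
        # uniform breathing about the centroid commutes with superposition
        # (optimal rotation stays the identity), so the aligned data are
        # exactly rank one
        coords, atoms = helix_atoms
        c = coords.mean(axis=0)
        frames = [(coords - c) * s + c for s in np.linspace(0.9, 1.1, 7)]
        res = pca_heavy_atoms(_traj_from(frames, atoms))
        assert res.variance_fractions[0] == pytest.approx(1.0, abs=1e-9)

    def test_variance_fractions_sum_to_one_and_match_eig_oracle(self, helix_atoms):
        coords, atoms = helix_atoms
        rng = np.random.default_rng(9)
        frames = [coords + rng.normal(0, 0.2, coords.shape) for _ in range(12)]
        traj = _traj_from(frames, atoms)
        res = pca_heavy_atoms(traj)
        assert res.variance_fractions.sum() == pytest.approx(1.0, abs=1e-9)
        G = res.modes @ res.modes.T
        np.testing.assert_allclose(G, np.eye(G.shape[0]), atol=1e-9)
        # oracle: align with our Kabsch, then dense covariance eigensolve
        aligned = []
        sel = AtomSelection(indices=np.arange(31))
        for f in range(traj.n_frames):
            R, t, _ = kabsch_superpose(traj.xyz[f], traj.xyz[0], sel)
            aligned.append((traj.xyz[f] @ R.T + t).ravel())
        X = np.asarray(aligned)
        C = np.cov(X, rowvar=False, ddof=1)
        evals = np.sort(np.linalg.eigvalsh(C))[::-1]
        k = res.eigenvalues.size
        np.testing.assert_allclose(res.eigenvalues, evals[:k], rtol=1e-9, atol=1e-12)

    def test_single_frame_rejected(self, helix_atoms):
        coords, atoms = helix_atoms
        with pytest.raises(ValueError):
            pca_heavy_atoms(_traj_from([coords], atoms))
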