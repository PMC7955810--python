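"""Ensemble metrics: superposition, RMSF, angles, H-bonds, shared-space PCA."""

import numpy as np
import pytest

from hdxdyn.dynamics import (
    Ensemble,
    HBondCriterion,
    HelixAxisDef,
    align_ensemble,
    hbond_occupancy,
    interhelix_angle,
    interhelix_angles,
    pca_shared_space,
    rmsf,
    rmsf_across_replicas,
)
from hdxdyn.synth import make_toy_ensemble

HELIX_A = HelixAxisDef("A", (1, 4), (9, 12))
HELIX_B = HelixAxisDef("B", (101, 104), (109, 112))


def _quaternion_superpose(mobile: np.ndarray, target: np.ndarray) -> float:
    """Independent superposition oracle: optimal RMSD via the Horn
    quaternion method (largest eigenvalue of the 4x4 key matrix)."""
    p = mobile - mobile.mean(axis=0)
    q = target - target.mean(axis=0)
    m = p.T @ q
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    key = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    lam = np.linalg.eigvalsh(key)[-1]
    e0 = (p**2).sum() + (q**2).sum()
    return float(np.sqrt(max(e0 - 2 * lam, 0.0) / len(p)))


class TestAlignment:
    def test_exact_recovery_of_rigid_transform(self):
        ens = make_toy_ensemble("static", n_frames=2, n_atoms=12, seed=0)
        from scipy.spatial.transform import Rotation

        rot = Rotation.random(random_state=5).as_matrix()
        ens.coords[1] = ens.coords[0] @ rot.T + np.array([4.0, -1.0, 9.0])
        out = align_ensemble(ens, 0)
        rmsd = np.sqrt(((out.coords[1] - out.coords[0]) ** 2).sum(axis=1).mean())
        assert rmsd <= 1e-6

    def test_idempotent_on_aligned_ensemble(self):
        ens = make_toy_ensemble("harmonic", n_frames=5, sd=0.2, seed=1)
        once = align_ensemble(ens, 0)
        twice = align_ensemble(once, 0)
        assert np.allclose(once.coords, twice.coords, atol=1e-9)

    def test_matches_quaternion_oracle(self):
        rng = np.random.default_rng(3)
        target = rng.normal(size=(10, 3))
        mobile = target + rng.normal(scale=0.3, size=(10, 3))
        ens = Ensemble(
            coords=np.stack([target, mobile]),
            resids=list(range(1, 11)),
            resnames=["ALA"] * 10,
            atom_names=["CA"] * 10,
            elements=["C"] * 10,
        )
        out = align_ensemble(ens, 0)
        rmsd = np.sqrt(((out.coords[1] - out.coords[0]) ** 2).sum(axis=1).mean())
        assert rmsd == pytest.approx(_quaternion_superpose(mobile, target), abs=1e-8)

    def test_too_few_atoms_rejected(self):
        ens = make_toy_ensemble("static", n_frames=2, n_atoms=5)
        with pytest.raises(ValueError):
            align_ensemble(ens, 0, selection=np.array([0, 1]))

    def test_proper_rotation_never_reflects(self):
        # a near-planar cloud invites improper solutions; chirality must survive
        rng = np.random.default_rng(8)
        base = rng.normal(size=(8, 3))
        base[:, 2] *= 0.01
        mirrored = base * np.array([1.0, 1.0, -1.0])
        ens = Ensemble(
            coords=np.stack([base, mirrored]),
            resids=list(range(1, 9)),
            resnames=["ALA"] * 8,
            atom_names=["CA"] * 8,
            elements=["C"] * 8,
        )
        out = align_ensemble(ens, 0)

        def chirality(v):
            return np.sign(np.dot(np.cross(v[1] - v[0], v[2] - v[0]), v[3] - v[0]))

        # a proper rotation can never flip the mobile frame's handedness,
        # even when a reflection would fit the near-planar cloud better
        assert chirality(out.coords[1]) == chirality(mirrored)


class TestRmsf:
    def test_static_ensemble_is_zero(self):
        assert rmsf(make_toy_ensemble("static", n_frames=50)).max() < 1e-12

    def test_two_point_alternation(self):
        coords = np.zeros((4, 1, 3))
        coords[::2, 0, 0] = 1.0
        coords[1::2, 0, 0] = -1.0
        ens = Ensemble(coords, [1], ["ALA"], ["CA"], ["C"])
        assert rmsf(ens)[0] == pytest.approx(1.0)

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError):
            rmsf(make_toy_ensemble("static", n_frames=1))

    def test_invariant_under_global_rigid_motion(self):
        ens = make_toy_ensemble("harmonic", n_frames=200, sd=0.4, seed=6)
        base = rmsf(ens)
        from scipy.spatial.transform import Rotation

        rot = Rotation.random(random_state=2).as_matrix()
        moved = ens.copy()
        moved.coords = ens.coords @ rot.T + np.array([5.0, 5.0, 5.0])
        assert np.allclose(rmsf(moved), base, atol=1e-10)

    def test_across_replica_quantiles(self):
        reps = [make_toy_ensemble("harmonic", n_frames=500, sd=0.3, seed=s) for s in (1, 2, 3)]
        out = rmsf_across_replicas(reps)
        assert out["per_replica"].shape == (3, 10)
        assert out["quantiles"].shape == (3, 10)
        assert np.all(out["quantiles"][0] <= out["quantiles"][2])
        assert out["n"] == 3


class TestAngles:
    @pytest.mark.parametrize("angle", [0.0, 37.0, 90.0, 180.0])
    def test_constructed_angles(self, angle):
        ens = make_toy_ensemble("helix_pair", n_frames=1, angle_deg=angle)
        assert interhelix_angle(ens, 0, HELIX_A, HELIX_B) == pytest.approx(angle, abs=1e-9)

    def test_helix_vs_itself_is_zero(self):
        ens = make_toy_ensemble("helix_pair", n_frames=1, angle_deg=45.0)
        assert interhelix_angle(ens, 0, HELIX_A, HELIX_A) == pytest.approx(0.0, abs=1e-9)

    def test_symmetric_in_arguments(self):
        ens = make_toy_ensemble("helix_pair", n_frames=1, angle_deg=63.0)
        ab = interhelix_angle(ens, 0, HELIX_A, HELIX_B)
        ba = interhelix_angle(ens, 0, HELIX_B, HELIX_A)
        assert ab == pytest.approx(ba, abs=1e-12)

    def test_invariant_to_uniform_scaling(self):
        ens = make_toy_ensemble("helix_pair", n_frames=1, angle_deg=63.0)
        scaled = ens.copy()
        scaled.coords *= 7.5
        assert interhelix_angle(scaled, 0, HELIX_A, HELIX_B) == pytest.approx(
            interhelix_angle(ens, 0, HELIX_A, HELIX_B), abs=1e-12
        )

    def test_per_frame_vector(self):
        ens = make_toy_ensemble("helix_pair", n_frames=7, angle_deg=90.0)
        angles = interhelix_angles(ens, HELIX_A, HELIX_B)
        assert angles.shape == (7,)
        assert np.allclose(angles, 90.0)


class TestHbonds:
    def test_always_formed_is_100(self):
        ens = make_toy_ensemble("hbond_triad", n_frames=40, formed_frames=40)
        occ = hbond_occupancy(ens, [((1, "N"), (1, "H"), (2, "O"))])
        assert occ[0]["occupancy_mean"] == 100.0

    def test_never_formed_is_0(self):
        ens = make_toy_ensemble("hbond_triad", n_frames=40, formed_frames=0, d_off=3.0)
        occ = hbond_occupancy(ens, [((1, "N"), (1, "H"), (2, "O"))])
        assert occ[0]["occupancy_mean"] == 0.0

    def test_exact_frame_counting(self):
        ens = make_toy_ensemble("hbond_triad", n_frames=100, formed_frames=71)
        occ = hbond_occupancy(ens, [((1, "N"), (1, "H"), (2, "O"))])
        assert occ[0]["occupancy_mean"] == pytest.approx(71.0)

    def test_frame_order_invariance(self):
        ens = make_toy_ensemble("hbond_triad", n_frames=50, formed_frames=20)
        shuffled = ens.copy()
        rng = np.random.default_rng(0)
        shuffled.coords = shuffled.coords[rng.permutation(50)]
        bond = [((1, "N"), (1, "H"), (2, "O"))]
        assert (
            hbond_occupancy(shuffled, bond)[0]["occupancy_mean"]
            == hbond_occupancy(ens, bond)[0]["occupancy_mean"]
        )

    def test_monotone_in_criterion(self):
        ens = make_toy_ensemble("hbond_triad", n_frames=60, formed_frames=25, d_off=2.8)
        bond = [((1, "N"), (1, "H"), (2, "O"))]
        loose = hbond_occupancy(ens, bond, HBondCriterion(3.0, 120.0))[0]["occupancy_mean"]
        tight = hbond_occupancy(ens, bond, HBondCriterion(2.5, 120.0))[0]["occupancy_mean"]
        tighter_angle = hbond_occupancy(ens, bond, HBondCriterion(3.0, 179.0))[0]["occupancy_mean"]
        assert loose >= tight
        assert loose >= tighter_angle

    def test_across_replica_statistics(self):
        reps = [
            make_toy_ensemble("hbond_triad", n_frames=10, formed_frames=k) for k in (5, 6, 7)
        ]
        occ = hbond_occupancy(reps, [((1, "N"), (1, "H"), (2, "O"))])[0]
        assert occ["occupancy_mean"] == pytest.approx(60.0)
        assert occ["n"] == 3
        assert occ["occupancy_sd"] == pytest.approx(np.std([50, 60, 70], ddof=1))

    def test_missing_hydrogen_rejected(self):
        ens = make_toy_ensemble("helix_pair", n_frames=2)
        with pytest.raises(ValueError, match="hydrogen"):
            hbond_occupancy(ens, [((1, "CA"), (2, "CA"), (3, "CA"))])


class TestPca:
    def test_single_direction_gives_full_pc1(self):
        base = np.zeros((20, 4, 3))
        shift = np.linspace(0, 5, 20)
        base[:, :, 0] = shift[:, None]
        ens = Ensemble(base, [1, 2, 3, 4], ["ALA"] * 4, ["CA"] * 4, ["C"] * 4)
        res = pca_shared_space([ens], n_components=3)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-12)

    def test_projections_of_concatenated_set_are_centered(self):
        a = make_toy_ensemble("harmonic", n_frames=30, sd=0.3, seed=1)
        b = make_toy_ensemble("harmonic", n_frames=50, sd=0.6, seed=2)
        res = pca_shared_space([a, b])
        stacked = np.vstack(res.projections)
        assert np.allclose(stacked.mean(axis=0), 0.0, atol=1e-9)

    def test_components_match_eigen_decomposition(self):
        coords = np.array(
            [
                [[0.0, 0.0, 0.0], [1.0, 1.0, 0.0]],
                [[1.0, 0.5, 0.0], [0.0, 0.2, 1.0]],
                [[0.3, 0.9, 0.4], [0.7, 0.1, 0.2]],
            ]
        )
        ens = Ensemble(coords, [1, 2], ["ALA"] * 2, ["CA"] * 2, ["C"] * 2)
        res = pca_shared_space([ens])
        flat = coords.reshape(3, -1)
        centered = flat - flat.mean(axis=0)
        cov = centered.T @ centered / (len(flat) - 1)
        w, v = np.linalg.eigh(cov)
        order = np.argsort(w)[::-1]
        for i in range(2):  # rank 2: three frames
            expected = v[:, order[i]]
            got = res.components[i]
            assert np.allclose(got, expected, atol=1e-9) or np.allclose(
                got, -expected, atol=1e-9
            )

    def test_explained_variance_sums_to_one(self):
        a = make_toy_ensemble("harmonic", n_frames=40, sd=0.3, seed=3)
        res = pca_shared_space([a])
        assert res.explained_variance_ratio.sum() == pytest.approx(1.0, abs=1e-9)

    def test_mismatched_selection_rejected(self):
        a = make_toy_ensemble("harmonic", n_frames=10, sd=0.1, n_atoms=5)
        b = make_toy_ensemble("harmonic", n_frames=10, sd=0.1, n_atoms=6)
        with pytest.raises(ValueError, match="mismatch"):
            pca_shared_space([a, b])


class TestEnsembleIO:
    def test_multimodel_pdb_roundtrip(self, tmp_path):
        ens = make_toy_ensemble("harmonic", n_frames=3, sd=0.5, seed=9)
        path = tmp_path / "ens.pdb"
        ens.to_pdb(path)
        back = Ensemble.from_pdb(path)
        assert back.n_frames == 3 and back.n_atoms == ens.n_atoms
        # PDB coordinates carry 3 decimals
        assert np.allclose(back.coords, ens.coords, atol=1e-3)
        assert list(back.resids) == list(ens.resids)
        assert list(back.atom_names) == list(ens.atom_names)
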