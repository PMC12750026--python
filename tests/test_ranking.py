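import numpy as np
import pytest

from anchordock.align import TemplateEnsemble, build_ensemble
from anchordock.fixtures import embed_reference, make_decoys
from anchordock.ranking import (ConfidenceModel, PoseCluster, butina_cluster,
                                fit_confidence, overlap_score, pose_features,
                                predict_confidence, rank, symmetry_rmsd)
from anchordock.sampling import Pose, Provenance
from anchordock.structures import ContractError, parse_small_molecule
from anchordock.templates import rank_templates
from oracles import butina_bruteforce


def pose_of(mol, xyz=None, **kw):
    m = mol.with_coords(xyz) if xyz is not None else mol.copy()
    return Pose(molecule=m, provenance=Provenance(), **kw)


def rotation_about_z(deg):
    t = np.deg2rad(deg)
    return np.array([[np.cos(t), -np.sin(t), 0],
                     [np.sin(t), np.cos(t), 0],
                     [0, 0, 1.0]])


@pytest.fixture(scope="module")
def benzene():
    return embed_reference("c1ccccc1", seed=2)


@pytest.fixture(scope="module")
def chain():
    # asymmetric rigid-ish molecule (no automorphisms beyond identity)
    return embed_reference("CCO", seed=2)


class TestSymmetryRmsd:
    def test_identical_zero(self, benzene):
        assert symmetry_rmsd(pose_of(benzene), pose_of(benzene)) == 0.0

    def test_benzene_ring_rotation_absorbed(self, benzene):
        xyz = benzene.coords()
        center = xyz.mean(axis=0)
        centered = xyz - center
        # rotate 60 degrees about the ring normal
        sv = np.linalg.svd(centered, compute_uv=True)
        normal = sv[2][2]
        t = np.deg2rad(60)
        K = np.array([[0, -normal[2], normal[1]],
                      [normal[2], 0, -normal[0]],
                      [-normal[1], normal[0], 0]])
        R = np.eye(3) + np.sin(t) * K + (1 - np.cos(t)) * (K @ K)
        rotated = centered @ R.T + center
        rmsd = symmetry_rmsd(pose_of(benzene), pose_of(benzene, rotated))
        assert rmsd < 0.05  # automorphism absorbs the ring rotation

    def test_single_displacement_closed_form(self, chain):
        xyz = chain.coords().copy()
        d = 0.9
        xyz[0] += np.array([d, 0, 0])
        n = len(xyz)
        expected = d / np.sqrt(n)
        got = symmetry_rmsd(pose_of(chain), pose_of(chain, xyz))
        assert got == pytest.approx(expected, abs=1e-9)

    def test_le_naive_rmsd(self, benzene):
        rng = np.random.default_rng(0)
        xyz = benzene.coords() + rng.normal(scale=0.7, size=(6, 3))
        a, b = pose_of(benzene), pose_of(benzene, xyz)
        naive = np.sqrt(((a.coords() - b.coords()) ** 2).sum(1).mean())
        assert symmetry_rmsd(a, b) <= naive + 1e-12

    def test_equals_naive_for_asymmetric(self, chain):
        rng = np.random.default_rng(1)
        xyz = chain.coords() + rng.normal(scale=0.5, size=(3, 3))
        a, b = pose_of(chain), pose_of(chain, xyz)
        naive = np.sqrt(((a.coords() - b.coords()) ** 2).sum(1).mean())
        assert symmetry_rmsd(a, b) == pytest.approx(naive, abs=1e-12)

    def test_graph_mismatch_rejected(self, benzene, chain):
        with pytest.raises(ContractError):
            symmetry_rmsd(pose_of(benzene), pose_of(chain))


def translated_poses(mol, shifts):
    out = []
    for i, s in enumerate(shifts):
        xyz = mol.coords() + np.array([s, 0.0, 0.0])
        out.append(pose_of(mol, xyz, energy=float(i)))
    return out


class TestButina:
    def test_all_identical_one_cluster(self, chain):
        poses = translated_poses(chain, [0, 0, 0, 0])
        clusters = butina_cluster(poses)
        assert len(clusters) == 1
        assert clusters[0].size == 4

    def test_two_poses_beyond_cutoff(self, chain):
        poses = translated_poses(chain, [0.0, 0.6])
        clusters = butina_cluster(poses, cutoff=0.5)
        assert len(clusters) == 2
        assert all(c.size == 1 for c in clusters)

    def test_chain_of_three_merges(self, chain):
        # AB = 0.4, BC = 0.4, AC = 0.8 -> B has most neighbours, one cluster
        poses = translated_poses(chain, [0.0, 0.4, 0.8])
        clusters = butina_cluster(poses, cutoff=0.5)
        assert len(clusters) == 1
        assert clusters[0].size == 3

    def test_inclusive_boundary(self, chain):
        poses = translated_poses(chain, [0.0, 0.5])
        clusters = butina_cluster(poses, cutoff=0.5)
        assert len(clusters) == 1

    def test_representative_lowest_energy(self, chain):
        poses = translated_poses(chain, [0.0, 0.1, 0.2])
        poses[2].energy = -5.0
        clusters = butina_cluster(poses)
        assert clusters[0].representative is poses[2]

    @pytest.mark.parametrize("seed", range(6))
    def test_agrees_with_bruteforce_oracle(self, chain, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 10))
        shifts = np.round(rng.uniform(0, 2.0, size=n), 3)
        poses = translated_poses(chain, shifts)
        dist = np.abs(shifts[:, None] - shifts[None, :])
        expect = butina_bruteforce(dist, 0.5)
        got = butina_cluster(poses, cutoff=0.5)
        got_sets = [sorted(poses.index(m) for m in c.members) for c in got]
        assert got_sets == expect

    def test_empty_rejected(self):
        with pytest.raises(ContractError):
            butina_cluster([])


class TestOverlap:
    def _ensemble(self, toy_system):
        ranked = rank_templates(toy_system.target_ligand, toy_system.templates)
        return build_ensemble(toy_system.target_receptor, ranked)

    def test_coincident_pose_full_overlap(self, toy_system):
        ens = self._ensemble(toy_system)
        pose = pose_of(toy_system.target_ligand)
        assert overlap_score(pose, ens) == 1.0

    def test_distant_pose_zero(self, toy_system):
        ens = self._ensemble(toy_system)
        xyz = toy_system.target_ligand.coords() + 50.0
        pose = pose_of(toy_system.target_ligand, xyz)
        assert overlap_score(pose, ens) == 0.0

    def test_half_overlap_constructed(self, toy_system):
        ens = self._ensemble(toy_system)
        lig = toy_system.target_ligand
        xyz = lig.coords().copy()
        n = len(xyz)
        half = n // 2
        xyz[:half] += 100.0  # move half far away
        pose = pose_of(lig, xyz)
        assert overlap_score(pose, ens) == pytest.approx((n - half) / n)

    def test_empty_ensemble_warns_zero(self, toy_system):
        ens = TemplateEnsemble(toy_system.target_receptor)
        with pytest.warns(UserWarning):
            assert overlap_score(pose_of(toy_system.target_ligand), ens) == 0.0

    def test_invariance_under_joint_rigid_motion(self, toy_system):
        ens = self._ensemble(toy_system)
        pose = pose_of(toy_system.target_ligand)
        base = overlap_score(pose, ens)
        R = rotation_about_z(25)
        t = np.array([3.0, -1.0, 2.0])
        moved_pose = pose_of(toy_system.target_ligand,
                             toy_system.target_ligand.coords() @ R.T + t)
        moved_ens = TemplateEnsemble(toy_system.target_receptor)
        import copy
        for m in ens.members:
            m2 = copy.copy(m)
            m2.ligand_in_target_frame = m.ligand_in_target_frame.with_coords(
                m.ligand_in_target_frame.coords() @ R.T + t)
            moved_ens.members.append(m2)
        assert overlap_score(moved_pose, moved_ens) == pytest.approx(base)


def planted_linear_decoys(toy_system, n=150, seed=0):
    """Decoys where true RMSD is exactly the anchor_rmsd feature."""
    rng = np.random.default_rng(seed)
    lig = toy_system.target_ligand
    rec = toy_system.target_receptor
    out = []
    for _ in range(n):
        r = float(rng.uniform(0.0, 6.0))
        pose = pose_of(lig, anchor_rmsd=r, overlap=0.0, energy=0.0)
        out.append((pose, rec, r))
    return out


class TestConfidence:
    def test_planted_linear_signal_near_zero_mse(self, toy_system):
        decoys = planted_linear_decoys(toy_system)
        model = fit_confidence(decoys, seed=1, alpha=1e-6)
        assert model.training_meta["holdout_mse"] < 1e-3
        assert model.training_meta["holdout_spearman"] > 0.99

    def test_sign_recovery(self, toy_system):
        decoys = planted_linear_decoys(toy_system)
        model = fit_confidence(decoys, seed=1, alpha=1e-6)
        i = list(model.feature_names).index("anchor_rmsd")
        assert model.coef[i] > 0  # generating coefficient is positive

    def test_nonnegative_output(self, toy_system):
        decoys = planted_linear_decoys(toy_system)
        model = fit_confidence(decoys, seed=1)
        pose = pose_of(toy_system.target_ligand, anchor_rmsd=0.0, overlap=1.0)
        assert predict_confidence(model, pose, toy_system.target_receptor) >= 0.0

    def test_near_native_scores_lower(self, toy_system):
        decoys = planted_linear_decoys(toy_system)
        model = fit_confidence(decoys, seed=1)
        rec = toy_system.target_receptor
        near = pose_of(toy_system.target_ligand, anchor_rmsd=0.1)
        far = pose_of(toy_system.target_ligand, anchor_rmsd=5.0)
        assert predict_confidence(model, near, rec) < \
            predict_confidence(model, far, rec)

    def test_invariance_under_joint_rigid_motion(self, toy_system):
        decoys = planted_linear_decoys(toy_system)
        model = fit_confidence(decoys, seed=1)
        rec = toy_system.target_receptor
        pose = pose_of(toy_system.target_ligand, anchor_rmsd=1.0, overlap=0.5)
        base = predict_confidence(model, pose, rec)
        R = rotation_about_z(40)
        t = np.array([1.0, 2.0, 3.0])
        moved_pose = pose_of(toy_system.target_ligand,
                             toy_system.target_ligand.coords() @ R.T + t,
                             anchor_rmsd=1.0, overlap=0.5)
        moved_rec = rec.transformed(R, t)
        assert predict_confidence(model, moved_pose, moved_rec) == \
            pytest.approx(base, abs=1e-9)

    def test_untrained_rejected(self, toy_system):
        with pytest.raises(ContractError):
            predict_confidence(ConfidenceModel(), pose_of(toy_system.target_ligand),
                               toy_system.target_receptor)

    def test_too_few_decoys_rejected(self, toy_system):
        with pytest.raises(ContractError):
            fit_confidence(planted_linear_decoys(toy_system, n=50))

    def test_degenerate_rmsd_range_rejected(self, toy_system):
        lig = toy_system.target_ligand
        rec = toy_system.target_receptor
        decoys = [(pose_of(lig, anchor_rmsd=1.0), rec, 1.0)] * 120
        with pytest.raises(ContractError):
            fit_confidence(decoys)

    def test_serialization_round_trip(self, toy_system):
        decoys = planted_linear_decoys(toy_system)
        model = fit_confidence(decoys, seed=1)
        back = ConfidenceModel.from_json(model.to_json())
        pose = pose_of(toy_system.target_ligand, anchor_rmsd=2.0, overlap=0.3)
        rec = toy_system.target_receptor
        assert predict_confidence(back, pose, rec) == \
            pytest.approx(predict_confidence(model, pose, rec), abs=1e-12)

    def test_imputation_of_unset_overlap(self, toy_system):
        pose = pose_of(toy_system.target_ligand)  # overlap unset
        feats = pose_features(pose, toy_system.target_receptor)
        i = list(("anchor_rmsd", "overlap")).index("overlap")
        assert feats[1] == 0.0
        assert np.all(np.isfinite(feats))


class TestRank:
    def _ensemble(self, toy_system):
        ranked = rank_templates(toy_system.target_ligand, toy_system.templates)
        return build_ensemble(toy_system.target_receptor, ranked)

    def _clusters(self, toy_system, sizes, shifts):
        lig = toy_system.target_ligand
        clusters = []
        for size, shift in zip(sizes, shifts):
            members = [pose_of(lig, lig.coords() + np.array([shift, 0, 0]),
                               energy=float(i)) for i in range(size)]
            clusters.append(PoseCluster(members))
        return clusters

    def test_single_cluster_rank_one(self, toy_system):
        ens = self._ensemble(toy_system)
        clusters = self._clusters(toy_system, [3], [0.0])
        out = rank(clusters, ens, None, toy_system.target_receptor)
        assert len(out) == 1 and out[0].rank == 1

    def test_larger_cluster_wins(self, toy_system):
        ens = self._ensemble(toy_system)
        clusters = self._clusters(toy_system, [10, 2], [0.0, 0.0])
        out = rank(clusters, ens, None, toy_system.target_receptor)
        assert out[0].cluster_size == 10

    def test_lower_predicted_rmsd_wins(self, toy_system):
        ens = self._ensemble(toy_system)
        clusters = self._clusters(toy_system, [5, 5], [0.0, 0.0])
        # planted model keyed on anchor_rmsd
        model = fit_confidence(planted_linear_decoys(toy_system), seed=1)
        clusters[0].members[0].anchor_rmsd = 4.0
        for m in clusters[0].members:
            m.anchor_rmsd = 4.0
        for m in clusters[1].members:
            m.anchor_rmsd = 1.0
        out = rank(clusters, ens, model, toy_system.target_receptor)
        assert out[0].predicted_rmsd < out[1].predicted_rmsd

    def test_ranks_contiguous_composite_monotone(self, toy_system):
        ens = self._ensemble(toy_system)
        clusters = self._clusters(toy_system, [8, 4, 2, 1], [0.0, 0.3, 3.0, 9.0])
        out = rank(clusters, ens, None, toy_system.target_receptor, top_n=4)
        assert [p.rank for p in out] == [1, 2, 3, 4]
        comps = [p.composite for p in out]
        assert all(a >= b - 1e-12 for a, b in zip(comps, comps[1:]))

    def test_top_n(self, toy_system):
        ens = self._ensemble(toy_system)
        clusters = self._clusters(toy_system, [1] * 8, np.linspace(0, 7, 8))
        out = rank(clusters, ens, None, toy_system.target_receptor, top_n=5)
        assert len(out) == 5
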