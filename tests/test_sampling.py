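import numpy as np
import pytest
from rdkit import Chem

from anchordock import engine
from anchordock.anchor import AnchorPattern, AnchorMapping, full_mcs_pattern, match_pattern
from anchordock.fixtures import embed_reference, make_flexible_ligand
from anchordock.sampling import (Pose, Provenance, SamplingConfig,
                                 clash_filter, derive_seed, embed_anchored,
                                 minimize_restrained,
                                 sample_torsions_anchored)
from anchordock.structures import ContractError, Receptor, Atom, parse_small_molecule
from anchordock.templates import compute_mcs, TemplateComplex


def mapping_for(target_smiles, anchor_atom_count=None, seed=9):
    """Anchor the target onto its own embedded reference conformer."""
    ref = embed_reference(target_smiles, seed=seed)
    ref.name = "tmpl"
    target = parse_small_molecule(target_smiles)
    mcs = compute_mcs(target, ref)
    template = TemplateComplex("tmpl", _empty_receptor(), ref, 1.0)
    pattern = full_mcs_pattern(mcs, template)
    if anchor_atom_count is not None and anchor_atom_count < len(pattern.coordinates):
        # trim to the first atoms of a chain pattern
        idx = list(range(anchor_atom_count))
        sub = AnchorPattern(
            smarts="-".join(["[CX4]"] * anchor_atom_count),
            coordinates=pattern.coordinates[idx],
            source_template_id="tmpl",
            component_sizes=(anchor_atom_count,))
        return target, match_pattern(sub, target, max_matches=1)[0]
    return target, match_pattern(pattern, target, max_matches=1)[0]


def _empty_receptor():
    return Receptor(atoms=[], chain_sequences={})


def _single_atom_receptor(xyz):
    return Receptor(
        atoms=[Atom("C", "CA", "ALA", 1, "", "A", np.array(xyz, float),
                    is_backbone=True)],
        chain_sequences={"A": "A"})


class TestEmbedAnchored:
    def test_fully_anchored_limit(self):
        target, mapping = mapping_for("Cc1ccc(CCO)cc1")
        cfg = SamplingConfig(n_max=5, seed=3)
        poses = embed_anchored(target, mapping, cfg)
        assert poses
        for p in poses:
            assert p.anchor_rmsd <= cfg.anchor_tolerance
            # all heavy atoms anchored -> pose pinned to anchor coords
            d = np.linalg.norm(
                p.coords()[list(mapping.target_atoms)] - mapping.anchor_coords,
                axis=1)
            assert d.max() <= 3 * cfg.anchor_tolerance

    def test_cap_respected(self):
        target, mapping = mapping_for("CCCCCCCCCCCCC", anchor_atom_count=3)
        cfg = SamplingConfig(n_max=15, seed=1)
        poses = embed_anchored(target, mapping, cfg)
        assert 0 < len(poses) <= 15

    def test_seed_reproducibility(self):
        target, mapping = mapping_for("CCCCCC", anchor_atom_count=3)
        cfg = SamplingConfig(n_max=8, seed=42)
        a = embed_anchored(target, mapping, cfg)
        b = embed_anchored(target, mapping, cfg)
        assert len(a) == len(b)
        for pa, pb in zip(a, b):
            np.testing.assert_array_equal(pa.coords(), pb.coords())

    def test_different_seeds_differ(self):
        target, mapping = mapping_for("CCCCCCCC", anchor_atom_count=3)
        a = embed_anchored(target, mapping, SamplingConfig(n_max=5, seed=1))
        b = embed_anchored(target, mapping, SamplingConfig(n_max=5, seed=2))
        assert not np.allclose(a[1].coords(), b[1].coords())

    def test_butane_terminal_anchor_torsion_scan(self):
        # both terminal carbons anchored: poses differ mainly in the
        # central torsion, anchors stay put
        ref = embed_reference("CCCC", seed=5)
        target = parse_small_molecule("CCCC")
        pattern = AnchorPattern(
            smarts="[CX4].[CX4]",
            coordinates=ref.coords()[[0, 3]],
            source_template_id="t", component_sizes=(1, 1))
        mappings = match_pattern(pattern, target)
        terminal = next(m for m in mappings
                        if sorted(m.target_atoms) == [0, 3])
        poses = embed_anchored(target, terminal,
                               SamplingConfig(n_max=10, seed=2))
        assert poses
        for p in poses:
            assert p.anchor_rmsd <= 0.25


class TestClashFilter:
    def _pose_at(self, dist):
        mol = parse_small_molecule("C").with_coords(np.array([[dist, 0.0, 0.0]]))
        return Pose(molecule=mol, provenance=Provenance())

    def test_discard_just_below_cutoff(self):
        rec = _single_atom_receptor((0, 0, 0))
        assert clash_filter(self._pose_at(1.49), rec) is False

    def test_retain_at_cutoff(self):
        rec = _single_atom_receptor((0, 0, 0))
        assert clash_filter(self._pose_at(1.50), rec) is True

    def test_retain_far(self):
        rec = _single_atom_receptor((0, 0, 0))
        assert clash_filter(self._pose_at(25.0), rec) is True

    def test_empty_receptor_retained(self):
        assert clash_filter(self._pose_at(0.0), _empty_receptor()) is True


class TestEngineGradients:
    def test_numerical_gradient_agreement(self):
        mol = embed_reference("Cc1ccc(CCO)cc1", seed=3)
        terms = engine.build_ligand_terms(mol.rdmol)
        model = engine.EnergyModel(terms)
        x = mol.coords() + 0.05
        e, g = model.energy_grad(x)
        num = np.zeros_like(g)
        h = 1e-6
        for i in range(x.shape[0]):
            for k in range(3):
                xp = x.copy(); xp[i, k] += h
                xm = x.copy(); xm[i, k] -= h
                num[i, k] = (model.energy(xp) - model.energy(xm)) / (2 * h)
        np.testing.assert_allclose(g, num, rtol=1e-4, atol=1e-4)


class TestMinimizeRestrained:
    def test_lj_pair_closed_form(self):
        # two atoms at 1.2*sigma relax toward the 2^(1/6)*sigma minimum
        sigma, eps = 3.4, 0.1
        pairs = np.array([[0, 1]])
        model = engine.EnergyModel([engine.LennardJones(
            pairs, np.array([sigma]), np.array([eps]))])
        x0 = np.array([[0.0, 0, 0], [1.2 * sigma, 0, 0]])
        x, e, _ = engine.minimize(model, x0, steps=500, grad_tol=1e-8)
        sep = np.linalg.norm(x[1] - x[0])
        assert sep == pytest.approx(2 ** (1 / 6) * sigma, abs=1e-3)
        assert e == pytest.approx(-eps, abs=1e-6)

    def test_backbone_frozen_bit_identical(self, toy_system, fast_sampling):
        target, mapping = mapping_for("Cc1ccc(CCO)cc1")
        pose = embed_anchored(target, mapping, fast_sampling)[0]
        rec = toy_system.target_receptor
        before = rec.heavy_coords().copy()
        minimize_restrained(pose, rec, fast_sampling)
        after = rec.heavy_coords()
        bb = rec.backbone_mask()
        assert np.array_equal(before[bb], after[bb])
        assert np.array_equal(before, after)  # engine works on copies

    def test_energy_never_increases(self, toy_system, fast_sampling):
        target, mapping = mapping_for("Cc1ccc(CCO)cc1")
        poses = embed_anchored(target, mapping, fast_sampling)[:3]
        for pose in poses:
            out = minimize_restrained(pose, toy_system.target_receptor,
                                      fast_sampling)
            assert out.energy is not None and np.isfinite(out.energy)

    def test_local_minimum_unchanged(self):
        sigma = 3.4
        model_factory = lambda x, frozen: engine.EnergyModel([
            engine.LennardJones(np.array([[0, 1]]), np.array([sigma]),
                                np.array([0.1]))], frozen)
        mol = parse_small_molecule("CC").with_coords(
            np.array([[0.0, 0, 0], [2 ** (1 / 6) * sigma, 0, 0]]))
        pose = Pose(molecule=mol, provenance=Provenance())
        cfg = SamplingConfig(minimize_steps=100, grad_tol=1e-4, seed=0)
        out = minimize_restrained(pose, _empty_receptor(), cfg,
                                  model_factory=model_factory)
        np.testing.assert_allclose(out.coords(), pose.coords(), atol=1e-6)
        assert out.minimize_iterations == 0

    def test_iteration_count_with_zero_tolerance(self):
        target, mapping = mapping_for("Cc1ccc(CCO)cc1")
        pose = embed_anchored(target, mapping,
                              SamplingConfig(n_max=1, seed=4))[0]
        # strain the pose so gradients stay finite and non-zero
        xyz = pose.coords()
        xyz[0] += 0.3
        strained = Pose(molecule=pose.molecule.with_coords(xyz),
                        provenance=pose.provenance,
                        anchor_atoms=pose.anchor_atoms,
                        anchor_coords=pose.anchor_coords)
        cfg = SamplingConfig(minimize_steps=25, grad_tol=0.0, seed=0)
        out = minimize_restrained(strained, _empty_receptor(), cfg)
        assert out.minimize_iterations == 25


class TestTorsionalSampler:
    def test_zero_magnitude_is_noop(self, fast_sampling):
        target, mapping = mapping_for("CCCCCC", anchor_atom_count=3)
        start = embed_anchored(target, mapping, fast_sampling)[0]
        out = sample_torsions_anchored(
            target, mapping, _empty_receptor(), steps=20, seed=1,
            cfg=fast_sampling, start_pose=start,
            max_magnitude=0.0, min_magnitude=0.0)
        for p in out:
            np.testing.assert_allclose(p.coords(), start.coords(), atol=1e-12)

    def test_no_free_rotatable_bond_returns_input(self, fast_sampling):
        target, mapping = mapping_for("c1ccccc1")
        start = embed_anchored(target, mapping, fast_sampling)[0]
        out = sample_torsions_anchored(
            target, mapping, _empty_receptor(), steps=10, seed=1,
            cfg=fast_sampling, start_pose=start)
        assert len(out) == 1
        np.testing.assert_array_equal(out[0].coords(), start.coords())

    def test_anchor_never_moves(self, fast_sampling):
        target, mapping = mapping_for("CCCCCCCC", anchor_atom_count=3)
        start = embed_anchored(target, mapping, fast_sampling)[0]
        out = sample_torsions_anchored(
            target, mapping, _empty_receptor(), steps=60, seed=3,
            cfg=fast_sampling, start_pose=start)
        idx = list(start.anchor_atoms)
        for p in out:
            np.testing.assert_allclose(p.coords()[idx],
                                       start.coords()[idx], atol=1e-9)
            assert p.anchor_rmsd <= fast_sampling.anchor_tolerance

    def test_topology_and_geometry_preserved(self, fast_sampling):
        target, mapping = mapping_for("CCCCCC", anchor_atom_count=3)
        start = embed_anchored(target, mapping, fast_sampling)[0]
        out = sample_torsions_anchored(
            target, mapping, _empty_receptor(), steps=40, seed=2,
            cfg=fast_sampling, start_pose=start)
        mol = start.molecule.rdmol
        bonds = [(b.GetBeginAtomIdx(), b.GetEndAtomIdx())
                 for b in mol.GetBonds()]
        ref = start.coords()
        for p in out:
            xyz = p.coords()
            assert Chem.MolToSmiles(p.molecule.rdmol) == Chem.MolToSmiles(mol)
            for i, j in bonds:
                d_ref = np.linalg.norm(ref[i] - ref[j])
                d_new = np.linalg.norm(xyz[i] - xyz[j])
                assert d_new == pytest.approx(d_ref, rel=1e-6)

    def test_butane_anneal_concentrates_near_staggered(self):
        # single free torsion with a 3-fold internal potential: long anneal
        # should end near a staggered minimum (cos(3*phi) = -1)
        from rdkit.Chem import rdMolTransforms
        target, mapping = mapping_for("CCCC", anchor_atom_count=3)
        cfg = SamplingConfig(n_max=1, seed=11)
        start = embed_anchored(target, mapping, cfg)[0]
        out = sample_torsions_anchored(
            target, mapping, _empty_receptor(), steps=400, seed=7,
            cfg=cfg, start_pose=start, keep_every=400)
        final = out[-1]
        conf = final.molecule.rdmol.GetConformer()
        phi = rdMolTransforms.GetDihedralDeg(conf, 0, 1, 2, 3)
        staggered_dist = min(abs(abs(phi) - 60), abs(abs(phi) - 180))
        assert staggered_dist < 25.0

    def test_deterministic(self, fast_sampling):
        target, mapping = mapping_for("CCCCCC", anchor_atom_count=3)
        start = embed_anchored(target, mapping, fast_sampling)[0]
        a = sample_torsions_anchored(target, mapping, _empty_receptor(),
                                     steps=30, seed=5, cfg=fast_sampling,
                                     start_pose=start)
        b = sample_torsions_anchored(target, mapping, _empty_receptor(),
                                     steps=30, seed=5, cfg=fast_sampling,
                                     start_pose=start)
        for pa, pb in zip(a, b):
            np.testing.assert_array_equal(pa.coords(), pb.coords())


def test_derive_seed_stable():
    assert derive_seed(7, "t1", 0) == derive_seed(7, "t1", 0)
    assert derive_seed(7, "t1", 0) != derive_seed(7, "t1", 1)
    assert derive_seed(7, "t1", 0) != derive_seed(8, "t1", 0)


def test_config_validation():
    with pytest.raises(ContractError):
        SamplingConfig(n_max=0)
    with pytest.raises(ContractError):
        SamplingConfig(clash_cutoff=-1.0)
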