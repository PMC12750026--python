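"""Synthetic test systems: a toy receptor pocket with holo templates,
sequences at controlled identity, and decoy pose sets of known RMSD.

Everything is regenerable from a seed; no external data is touched.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .align import kabsch
from .sampling import Pose, Provenance
from .structures import Atom, ContractError, Receptor, SmallMolecule
from .templates import TemplateComplex, compute_sequence_identity

logger = logging.getLogger(__name__)

__all__ = [
    "ToySystem", "make_toy_system", "mutate_sequence", "make_decoys",
    "make_flexible_ligand", "embed_reference", "make_confidence_benchmark",
]

AMINO_LETTERS = "ACDEFGHIKLMNPQRSTVWY"
ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}

TARGET_SMILES = "Cc1ccc(CCO)cc1"       # ring scaffold + short flexible tail
TEMPLATE_SMILES = {
    "tmpl_self": "Cc1ccc(CCO)cc1",     # identical to the target
    "tmpl_xylene": "Cc1ccc(C)cc1",     # shares the ring + para methyls
}
TEMPLATE_IDENTITIES = {"tmpl_self": 0.90, "tmpl_xylene": 0.70}
LOW_IDENTITY_TEMPLATE = ("tmpl_far", "Cc1ccc(C)cc1", 0.40)

# ideal residue template: backbone N, CA, C, O plus CB (local frame, Angstrom)
_RES_TEMPLATE = np.array([
    [-0.525, 1.363, 0.000],   # N
    [0.000, 0.000, 0.000],    # CA
    [1.526, 0.000, 0.000],    # C
    [2.153, 1.062, 0.000],    # O
    [-0.507, -0.776, -1.212], # CB
])
_RES_ATOM_NAMES = ("N", "CA", "C", "O", "CB")


def mutate_sequence(seq: str, identity_target: float, seed: int = 0) -> str:
    """Substitute exactly floor(len*(1-identity_target)) positions, never
    to the original letter; deterministic per seed."""
    if not (0.0 < identity_target <= 1.0):
        raise ContractError("identity_target must be in (0, 1]")
    n_sub = int(np.floor(len(seq) * (1.0 - identity_target) + 1e-9))
    rng = np.random.default_rng(seed)
    positions = rng.choice(len(seq), size=n_sub, replace=False)
    out = list(seq)
    for p in positions:
        choices = [c for c in AMINO_LETTERS if c != seq[p]]
        out[p] = choices[rng.integers(len(choices))]
    return "".join(out)


def _random_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(AMINO_LETTERS[i]
                   for i in rng.integers(0, len(AMINO_LETTERS), size=length))


def _pocket_receptor(sequence: str, rng: np.random.Generator,
                     radius: float = 11.0, chain: str = "A") -> Receptor:
    """Residues on a spherical shell around the origin, CB pointing inward."""
    n_res = len(sequence)
    atoms: list[Atom] = []
    # Fibonacci shell for even coverage
    golden = np.pi * (3.0 - np.sqrt(5.0))
    for i, letter in enumerate(sequence):
        zf = 1.0 - 2.0 * (i + 0.5) / n_res
        r = np.sqrt(max(1.0 - zf * zf, 0.0))
        theta = golden * i
        center = radius * np.array([r * np.cos(theta), r * np.sin(theta), zf])
        inward = -center / np.linalg.norm(center)
        # orthonormal frame with z ~ inward
        ref = np.array([0.0, 0.0, 1.0])
        if abs(inward @ ref) > 0.95:
            ref = np.array([1.0, 0.0, 0.0])
        e1 = np.cross(inward, ref)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(inward, e1)
        frame = np.stack([e1, e2, inward], axis=1)
        res_name = ONE_TO_THREE[letter]
        names = _RES_ATOM_NAMES[:4] if res_name == "GLY" else _RES_ATOM_NAMES
        for name, local in zip(names, _RES_TEMPLATE):
            xyz = center + frame @ local
            atoms.append(Atom(
                element=name[0], name=name, res_name=res_name,
                res_seq=i + 1, i_code="", chain=chain, xyz=xyz,
                is_backbone=name in ("N", "CA", "C", "O"), is_hetero=False))
    return Receptor(atoms, {chain: sequence})


def embed_reference(smiles: str, seed: int, center=None) -> SmallMolecule:
    """Embed one conformer of *smiles*, optionally re-centred at *center*."""
    mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
    cid = AllChem.EmbedMolecule(mol, randomSeed=seed)
    if cid != 0:
        raise RuntimeError(f"embedding failed for {smiles}")
    AllChem.MMFFOptimizeMolecule(mol, maxIters=200)
    heavy = Chem.RemoveHs(mol)
    xyz = np.array(heavy.GetConformer().GetPositions())
    if center is not None:
        xyz = xyz - xyz.mean(axis=0) + np.asarray(center, dtype=float)
    sm = SmallMolecule(Chem.MolFromSmiles(smiles))
    return sm.with_coords(xyz)


def make_flexible_ligand(seed: int = 0) -> SmallMolecule:
    """A 10-rotatable-bond chain ligand with an embedded conformer."""
    return embed_reference("CCCCCCCCCCCCC", seed, center=(0.0, 0.0, 0.0))


@dataclass
class ToySystem:
    target_receptor: Receptor
    target_ligand: SmallMolecule          # graph + reference pose conformer
    reference_pose: Pose
    templates: list[TemplateComplex]
    low_identity_template: TemplateComplex
    seed: int = 0

    @property
    def all_templates(self) -> list[TemplateComplex]:
        return [*self.templates, self.low_identity_template]


def _align_ring_onto(reference: SmallMolecule, mobile: SmallMolecule) -> SmallMolecule:
    """Rigidly place *mobile* so its aromatic ring sits on the reference's."""
    ref_ring = [a.GetIdx() for a in reference.rdmol.GetAtoms() if a.GetIsAromatic()]
    mob_ring = [a.GetIdx() for a in mobile.rdmol.GetAtoms() if a.GetIsAromatic()]
    n = min(len(ref_ring), len(mob_ring))
    t = kabsch(mobile.coords()[mob_ring[:n]], reference.coords()[ref_ring[:n]])
    return mobile.with_coords(t.apply(mobile.coords()), name=mobile.name)


def make_toy_system(seed: int = 0) -> ToySystem:
    """Deterministic toy docking system.

    A 30-residue pocket on an 11-Angstrom shell around the origin, a
    reference ligand pose at the pocket centre, one template identical to
    the target complex, a second scaffold-sharing template, and one
    template below the 50% identity threshold.
    """
    rng = np.random.default_rng(seed)
    target_seq = _random_sequence(30, rng)
    target_receptor = _pocket_receptor(target_seq, rng)

    reference = embed_reference(TARGET_SMILES, seed=seed + 17, center=(0, 0, 0))
    reference.name = "reference"
    ref_pose = Pose(molecule=reference.copy(),
                    provenance=Provenance(template_id="reference"))

    templates: list[TemplateComplex] = []
    for i, (tid, smi) in enumerate(sorted(TEMPLATE_SMILES.items())):
        identity = TEMPLATE_IDENTITIES[tid]
        mut_seq = mutate_sequence(target_seq, identity, seed=seed + 101 + i)
        t_receptor = _pocket_receptor(mut_seq, rng)
        if tid == "tmpl_self":
            ligand = reference.copy()
        else:
            ligand = embed_reference(smi, seed=seed + 31 + i, center=(0, 0, 0))
            ligand = _align_ring_onto(reference, ligand)
        ligand.name = tid
        templates.append(TemplateComplex(
            source_id=tid, receptor=t_receptor, ligand=ligand,
            identity=compute_sequence_identity(target_seq, mut_seq)))

    fid, fsmi, fident = LOW_IDENTITY_TEMPLATE
    far_seq = mutate_sequence(target_seq, fident, seed=seed + 199)
    far_ligand = embed_reference(fsmi, seed=seed + 41, center=(0, 0, 0))
    far_ligand = _align_ring_onto(reference, far_ligand)
    far_ligand.name = fid
    low = TemplateComplex(
        source_id=fid, receptor=_pocket_receptor(far_seq, rng),
        ligand=far_ligand,
        identity=compute_sequence_identity(target_seq, far_seq))

    system = ToySystem(
        target_receptor=target_receptor,
        target_ligand=reference,
        reference_pose=ref_pose,
        templates=templates,
        low_identity_template=low,
        seed=seed,
    )
    _check_clearance(system)
    return system


def _check_clearance(system: ToySystem, min_dist: float = 3.0) -> None:
    rec = system.target_receptor.heavy_coords()
    for t in system.templates:
        lig = t.ligand.coords()
        d = np.linalg.norm(rec[:, None, :] - lig[None, :, :], axis=2).min()
        if d < min_dist:
            raise RuntimeError(
                f"fixture template {t.source_id} too close to receptor ({d:.2f} A)")


def make_confidence_benchmark(system: ToySystem, n: int = 500,
                              rmsd_max: float = 8.0, seed: int = 0):
    """Decoy benchmark for the RMSD-confidence model.

    Returns (decoys, labels are embedded): a list of
    (Pose, receptor, true RMSD) with anchor_rmsd, overlap and energy
    features populated, spanning RMSD 0..rmsd_max.
    """
    from . import engine
    from .align import build_ensemble
    from .ranking import overlap_score
    from .templates import rank_templates

    ranked = rank_templates(system.target_ligand, system.templates)
    ensemble = build_ensemble(system.target_receptor, ranked)
    reference = system.reference_pose
    ref_xyz = reference.coords()
    anchor_atoms = tuple(
        a.GetIdx() for a in reference.molecule.rdmol.GetAtoms()
        if a.GetIsAromatic())

    n_targets = max(n // 10, 1)
    targets = np.linspace(0.0, rmsd_max, n_targets)
    raw = make_decoys(reference, list(targets), n_per_target=10, seed=seed)

    model = engine.EnergyModel(
        engine.build_ligand_terms(reference.molecule.rdmol))
    out = []
    for pose, label in raw[:n]:
        idx = np.array(anchor_atoms, dtype=int)
        pose.anchor_atoms = anchor_atoms
        pose.anchor_coords = ref_xyz[idx]
        pose.anchor_rmsd = float(np.sqrt(
            ((pose.coords()[idx] - ref_xyz[idx]) ** 2).sum(axis=1).mean()))
        pose.overlap = overlap_score(pose, ensemble)
        pose.energy = float(model.energy(pose.coords()))
        out.append((pose, system.target_receptor, label))
    return out


def _perturb(xyz: np.ndarray, scale: float, rot_axis: np.ndarray,
             trans_dir: np.ndarray, torsion_deltas: np.ndarray,
             torsions: list[tuple[int, int, np.ndarray]]) -> np.ndarray:
    from .sampling import _rotate_about_axis
    out = xyz.copy()
    for (j, k, mask), delta in zip(torsions, torsion_deltas):
        out = _rotate_about_axis(out, mask, out[j], out[k], float(delta * scale))
    centroid = out.mean(axis=0)
    angle = scale * 0.6
    axis = rot_axis / np.linalg.norm(rot_axis)
    c, s = np.cos(angle), np.sin(angle)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    R = np.eye(3) + s * K + (1 - c) * (K @ K)
    out = (out - centroid) @ R.T + centroid
    out = out + trans_dir * scale * 4.0
    return out


def make_decoys(reference: Pose, rmsd_targets: list[float],
                n_per_target: int = 1, seed: int = 0,
                tolerance: float = 0.1) -> list[tuple[Pose, float]]:
    """Decoys at requested symmetry-RMSD values from *reference*.

    Built by random rigid jitter plus torsion perturbation, with the
    perturbation scale bisected until the achieved RMSD is within
    *tolerance* of the request; the label is the achieved value.
    """
    from .ranking import symmetry_rmsd
    from .sampling import _rotatable_bonds_outside_anchor

    if reference.molecule.num_conformers != 1:
        raise ContractError("reference pose needs exactly one conformer")
    rng = np.random.default_rng(seed)
    mol = reference.molecule.rdmol
    torsions = _rotatable_bonds_outside_anchor(mol, set())
    xyz0 = reference.coords()
    out: list[tuple[Pose, float]] = []
    for target in rmsd_targets:
        made = 0
        for rep in range(n_per_target):
            if target <= 1e-9:
                decoy = Pose(molecule=reference.molecule.copy(),
                             provenance=Provenance(generator="decoy"))
                out.append((decoy, 0.0))
                made += 1
                continue
            rot_axis = rng.normal(size=3)
            trans_dir = rng.normal(size=3)
            trans_dir /= np.linalg.norm(trans_dir)
            torsion_deltas = rng.normal(size=len(torsions)) if torsions else np.zeros(0)

            def achieved(scale: float) -> tuple[float, np.ndarray]:
                xyz = _perturb(xyz0, scale, rot_axis, trans_dir,
                               torsion_deltas, torsions)
                decoy = Pose(molecule=reference.molecule.with_coords(xyz),
                             provenance=Provenance(generator="decoy"))
                return symmetry_rmsd(decoy, reference), xyz

            lo, hi = 0.0, 4.0
            r_hi, _ = achieved(hi)
            grow = 0
            while r_hi < target and grow < 6:
                hi *= 2.0
                r_hi, _ = achieved(hi)
                grow += 1
            if r_hi < target - tolerance:
                warnings.warn(f"decoy target {target} A unreachable; skipped")
                continue
            best = None
            for _ in range(60):
                mid = 0.5 * (lo + hi)
                r_mid, xyz = achieved(mid)
                best = (r_mid, xyz)
                if abs(r_mid - target) <= tolerance * 0.5:
                    break
                if r_mid < target:
                    lo = mid
                else:
                    hi = mid
            r_final, xyz = best
            if abs(r_final - target) > tolerance:
                warnings.warn(f"decoy target {target} A missed "
                              f"({r_final:.3f} A); skipped")
                continue
            decoy = Pose(molecule=reference.molecule.with_coords(xyz),
                         provenance=Provenance(generator="decoy"))
            out.append((decoy, float(r_final)))
            made += 1
    return out
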