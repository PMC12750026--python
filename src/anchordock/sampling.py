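"""Anchored conformer generation, steric clash filtering, restrained
minimization, and the annealed anchored torsional sampler.

Anchor atoms are held by hard coordinate constraints during embedding
and by harmonic restraints (default 10 kcal/mol/A^2) during
minimization; a pose is accepted when its anchor RMSD after a rigid fit
of the anchor atoms is within the tolerance (default 0.25 A).
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem
from rdkit.Geometry import Point3D
from scipy.spatial import cKDTree

from . import engine
from .anchor import AnchorMapping
from .structures import ContractError, Receptor, SmallMolecule

logger = logging.getLogger(__name__)

__all__ = [
    "SamplingConfig", "Provenance", "Pose",
    "embed_anchored", "clash_filter", "minimize_restrained",
    "sample_torsions_anchored", "derive_seed",
]


@dataclass
class SamplingConfig:
    n_max: int = 1000                  # conformer cap per atomic mapping
    clash_cutoff: float = 1.5          # Angstrom, strict <
    minimize_steps: int = 500
    anchor_tolerance: float = 0.25     # Angstrom
    restraint_k: float = 10.0          # kcal/mol/A^2
    seed: int = 0
    grad_tol: float = 1e-4
    retry_factor: int = 3              # embedding attempts = retry_factor * n_max
    sidechain_tether_k: float = 5.0
    sidechain_radius: float = 8.0      # receptor side chains mobile within this of the anchor

    def __post_init__(self):
        for name in ("n_max", "clash_cutoff", "minimize_steps",
                     "anchor_tolerance", "restraint_k"):
            if getattr(self, name) <= 0:
                raise ContractError(f"{name} must be positive")


@dataclass
class Provenance:
    template_id: str = ""
    pattern_id: str = ""
    match_index: int = 0
    generator: str = "embed"           # embed | torsional


@dataclass
class Pose:
    molecule: SmallMolecule            # exactly one conformer
    provenance: Provenance = field(default_factory=Provenance)
    anchor_rmsd: float = 0.0
    clash: bool = False
    energy: float | None = None
    overlap: float | None = None
    predicted_rmsd: float | None = None
    anchor_atoms: tuple[int, ...] = ()
    anchor_coords: np.ndarray | None = None
    minimize_iterations: int | None = None

    def __post_init__(self):
        if self.molecule.num_conformers != 1:
            raise ContractError("a pose carries exactly one conformer")
        if self.anchor_rmsd < 0:
            raise ContractError("anchor_rmsd must be nonnegative")

    def coords(self) -> np.ndarray:
        return self.molecule.coords()

    def extra_tags(self) -> dict[str, str]:
        return {}


def derive_seed(seed: int, template_id: str, match_index: int) -> int:
    """Per-mapping sub-seed: top seed xor a stable hash of the provenance."""
    h = hashlib.sha256(f"{template_id}:{match_index}".encode()).digest()
    return (seed ^ int.from_bytes(h[:4], "big")) & 0x7FFFFFFF


def _rigid_fit_onto_anchor(xyz: np.ndarray, anchor_atoms: np.ndarray,
                           anchor_ref: np.ndarray) -> tuple[np.ndarray, float]:
    """Rigidly fit the whole conformer so its anchor atoms sit on the
    reference anchor coordinates; returns (moved coords, anchor rmsd)."""
    A = xyz[anchor_atoms]
    ca, cr = A.mean(axis=0), anchor_ref.mean(axis=0)
    H = (A - ca).T @ (anchor_ref - cr)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    moved = (xyz - ca) @ R.T + cr
    rmsd = float(np.sqrt(((moved[anchor_atoms] - anchor_ref) ** 2).sum(axis=1).mean()))
    return moved, rmsd


def embed_anchored(target: SmallMolecule, mapping: AnchorMapping,
                   cfg: SamplingConfig) -> list[Pose]:
    """ETKDG distance-geometry embedding with anchor atoms constrained to
    their template coordinates.

    Emits at most ``cfg.n_max`` poses per mapping; each pose is rigidly
    fitted onto the anchor and accepted only when anchor RMSD is within
    ``cfg.anchor_tolerance``.  Fully deterministic for a fixed seed.
    """
    anchor_atoms = np.array(mapping.target_atoms, dtype=int)
    anchor_ref = np.asarray(mapping.anchor_coords, dtype=float)
    molH = Chem.AddHs(target.rdmol)
    cmap = {int(i): Point3D(*map(float, anchor_ref[k]))
            for k, i in enumerate(anchor_atoms)}
    sub_seed = derive_seed(cfg.seed, mapping.pattern.source_template_id,
                           mapping.match_index)
    poses: list[Pose] = []
    attempts_left = cfg.retry_factor * cfg.n_max
    batch_seed = sub_seed
    while len(poses) < cfg.n_max and attempts_left > 0:
        want = min(cfg.n_max - len(poses), attempts_left)
        mol = Chem.Mol(molH)
        cids = AllChem.EmbedMultipleConfs(
            mol, numConfs=want, coordMap=cmap, randomSeed=int(batch_seed) + 1,
            useRandomCoords=False, enforceChirality=True, numThreads=1)
        attempts_left -= want
        batch_seed += 1
        if len(cids) == 0:
            continue
        heavy = Chem.RemoveHs(mol)
        for cid in cids:
            xyz = np.array(heavy.GetConformer(int(cid)).GetPositions())
            moved, a_rmsd = _rigid_fit_onto_anchor(xyz, anchor_atoms, anchor_ref)
            if a_rmsd > cfg.anchor_tolerance:
                continue
            pose = Pose(
                molecule=target.with_coords(moved),
                provenance=Provenance(
                    template_id=mapping.pattern.source_template_id,
                    pattern_id=mapping.pattern.smarts,
                    match_index=mapping.match_index,
                    generator="embed"),
                anchor_rmsd=a_rmsd,
                anchor_atoms=tuple(int(i) for i in anchor_atoms),
                anchor_coords=anchor_ref,
            )
            poses.append(pose)
            if len(poses) >= cfg.n_max:
                break
    if not poses:
        warnings.warn("anchored embedding produced no acceptable conformer")
    return poses


def clash_filter(pose: Pose, receptor: Receptor, cutoff: float = 1.5) -> bool:
    """True when the pose is retained.

    A pose is discarded iff any ligand-heavy/receptor-heavy distance is
    strictly below *cutoff*; hydrogens are ignored on both sides.
    """
    rec_xyz = receptor.heavy_coords(polymer_only=True)
    if rec_xyz.shape[0] == 0:
        return True
    tree = _receptor_tree(receptor)
    dmin, _ = tree.query(pose.coords(), k=1)
    retained = bool(np.min(dmin) >= cutoff)
    pose.clash = not retained
    return retained


_TREE_CACHE: dict[int, cKDTree] = {}


def _receptor_tree(receptor: Receptor) -> cKDTree:
    key = id(receptor)
    tree = _TREE_CACHE.get(key)
    if tree is None:
        tree = cKDTree(receptor.heavy_coords(polymer_only=True))
        _TREE_CACHE.clear()
        _TREE_CACHE[key] = tree
    return tree


def _mobile_sidechain_indices(receptor: Receptor, center: np.ndarray,
                              radius: float) -> np.ndarray:
    atoms = receptor.polymer_atoms
    if not atoms:
        return np.zeros(0, dtype=int)
    xyz = receptor.heavy_coords(polymer_only=True)
    near = np.linalg.norm(xyz - center, axis=1) <= radius
    side = ~receptor.backbone_mask()
    return np.where(near & side)[0]


def minimize_restrained(pose: Pose, receptor: Receptor, cfg: SamplingConfig,
                        extra_restraints: list[tuple[int, np.ndarray]] | None = None,
                        model_factory=None) -> Pose:
    """Restrained minimization with the internal engine.

    Receptor backbone atoms are frozen (bit-identical before and after);
    side chains within ``cfg.sidechain_radius`` of the ligand move under
    a positional tether.  Anchor atoms and user-declared coordination
    atoms carry harmonic restraints of stiffness ``cfg.restraint_k``.
    A different engine honouring the same contract may be injected via
    *model_factory(combined_xyz, frozen_mask) -> EnergyModel*.
    """
    lig_xyz = pose.coords()
    n_lig = len(lig_xyz)
    rec_atoms = receptor.polymer_atoms
    rec_xyz = receptor.heavy_coords(polymer_only=True)
    combined = np.vstack([lig_xyz, rec_xyz]) if len(rec_atoms) else lig_xyz.copy()

    frozen = np.zeros(len(combined), dtype=bool)
    if len(rec_atoms):
        mobile = set(_mobile_sidechain_indices(
            receptor, lig_xyz.mean(axis=0), cfg.sidechain_radius).tolist())
        for j in range(len(rec_atoms)):
            if j not in mobile:
                frozen[n_lig + j] = True

    if model_factory is not None:
        model = model_factory(combined, frozen)
    else:
        terms = engine.build_ligand_terms(pose.molecule.rdmol)
        if len(rec_atoms):
            lig_elems = [a.GetSymbol() for a in pose.molecule.rdmol.GetAtoms()]
            rec_elems = [a.element for a in rec_atoms]
            terms.append(engine.ligand_receptor_lj(lig_elems, 0, rec_elems, n_lig))
            side_idx = np.array(sorted(
                j for j in range(len(rec_atoms)) if not frozen[n_lig + j]),
                dtype=int)
            if side_idx.size:
                terms.append(engine.Tethers(
                    side_idx + n_lig, rec_xyz[side_idx], cfg.sidechain_tether_k))
        if pose.anchor_atoms:
            terms.append(engine.Tethers(
                np.array(pose.anchor_atoms, dtype=int),
                np.asarray(pose.anchor_coords, dtype=float),
                cfg.restraint_k))
        for idx, ref in (extra_restraints or []):
            terms.append(engine.Tethers(
                np.array([idx], dtype=int), np.asarray(ref, float).reshape(1, 3),
                cfg.restraint_k))
        model = engine.EnergyModel(terms, frozen)

    e_in = model.energy(combined)
    if not np.isfinite(e_in):
        raise ContractError("non-finite energy at input pose")
    x, e_out, iterations = engine.minimize(
        model, combined, cfg.minimize_steps, cfg.grad_tol)
    assert e_out <= e_in + 1e-9
    new_xyz = x[:n_lig]
    a_rmsd = pose.anchor_rmsd
    if pose.anchor_atoms:
        idx = np.array(pose.anchor_atoms, dtype=int)
        a_rmsd = float(np.sqrt(
            ((new_xyz[idx] - pose.anchor_coords) ** 2).sum(axis=1).mean()))
    out = replace(
        pose,
        molecule=pose.molecule.with_coords(new_xyz),
        energy=float(e_out),
        anchor_rmsd=a_rmsd,
        minimize_iterations=iterations,
    )
    return out


def _rotatable_bonds_outside_anchor(mol: Chem.Mol,
                                    anchor_atoms: set[int]) -> list[tuple[int, int, np.ndarray]]:
    """Rotatable bonds with a rotatable side free of anchor atoms.

    Returns (j, k, side_mask) where side_mask marks the atoms rotated
    about the j->k axis; the rotated side never contains an anchor atom.
    """
    out = []
    n = mol.GetNumAtoms()
    for b in mol.GetBonds():
        if b.IsInRing() or b.GetBondType() != Chem.BondType.SINGLE:
            continue
        j, k = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        if mol.GetAtomWithIdx(j).GetDegree() < 2 or mol.GetAtomWithIdx(k).GetDegree() < 2:
            continue
        # partition atoms by removing bond j-k
        side_k = _component_from(mol, k, exclude_edge=(j, k))
        side_j = set(range(n)) - side_k
        for axis_j, axis_k, side in ((j, k, side_k), (k, j, side_j)):
            rotated = side - {axis_k}
            if rotated and not (rotated & anchor_atoms):
                mask = np.zeros(n, dtype=bool)
                mask[sorted(rotated)] = True
                out.append((axis_j, axis_k, mask))
                break
    return out


def _component_from(mol: Chem.Mol, start: int,
                    exclude_edge: tuple[int, int]) -> set[int]:
    seen = {start}
    stack = [start]
    while stack:
        i = stack.pop()
        for nb in mol.GetAtomWithIdx(i).GetNeighbors():
            jj = nb.GetIdx()
            if {i, jj} == set(exclude_edge):
                continue
            if jj not in seen:
                seen.add(jj)
                stack.append(jj)
    return seen


def _rotate_about_axis(xyz: np.ndarray, mask: np.ndarray, p0: np.ndarray,
                       p1: np.ndarray, angle: float) -> np.ndarray:
    axis = p1 - p0
    axis = axis / np.linalg.norm(axis)
    c, s = np.cos(angle), np.sin(angle)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    R = np.eye(3) + s * K + (1 - c) * (K @ K)
    out = xyz.copy()
    out[mask] = (xyz[mask] - p0) @ R.T + p0
    return out


def sample_torsions_anchored(target: SmallMolecule, mapping: AnchorMapping,
                             receptor: Receptor, steps: int = 200,
                             seed: int = 0,
                             cfg: SamplingConfig | None = None,
                             start_pose: Pose | None = None,
                             keep_every: int = 20,
                             max_magnitude: float = np.pi,
                             min_magnitude: float = 0.05) -> list[Pose]:
    """Annealed Metropolis sampling of torsions outside the anchor.

    Starting from an embedded pose, free torsions are perturbed with a
    magnitude annealed from pi down to 0.05 rad over *steps* stages and
    accepted on the internal ligand energy plus the receptor interaction.
    Anchor atoms never move, so bond lengths/angles and the anchor are
    preserved exactly.  With no free rotatable bond the input pose is
    returned unchanged.
    """
    cfg = cfg or SamplingConfig(seed=seed)
    if start_pose is None:
        embedded = embed_anchored(target, mapping, replace(cfg, n_max=1))
        if not embedded:
            return []
        start_pose = embedded[0]
    mol = start_pose.molecule.rdmol
    anchor_atoms = set(start_pose.anchor_atoms or mapping.target_atoms)
    bonds = _rotatable_bonds_outside_anchor(mol, anchor_atoms)
    if not bonds:
        return [start_pose]

    terms = engine.build_ligand_terms(mol)
    rec_atoms = receptor.polymer_atoms
    if rec_atoms:
        lig_elems = [a.GetSymbol() for a in mol.GetAtoms()]
        rec_elems = [a.element for a in rec_atoms]
        terms.append(engine.ligand_receptor_lj(
            lig_elems, 0, rec_elems, mol.GetNumAtoms()))
        rec_xyz = receptor.heavy_coords(polymer_only=True)
    else:
        rec_xyz = np.zeros((0, 3))
    model = engine.EnergyModel(terms)

    def total_energy(lig_xyz):
        combined = np.vstack([lig_xyz, rec_xyz]) if len(rec_xyz) else lig_xyz
        return model.energy(combined)

    rng = np.random.default_rng(seed)
    xyz = start_pose.coords().copy()
    e = total_energy(xyz)
    out: list[Pose] = []
    for stage in range(steps):
        frac = stage / max(steps - 1, 1)
        magnitude = max_magnitude * (1.0 - frac) + min_magnitude * frac
        temperature = max(3.0 * (1.0 - frac), 0.05)
        j, k, mask = bonds[rng.integers(len(bonds))]
        delta = rng.normal(0.0, magnitude)
        trial = _rotate_about_axis(xyz, mask, xyz[j], xyz[k], delta)
        e_trial = total_energy(trial)
        if e_trial <= e or rng.random() < np.exp(-(e_trial - e) / temperature):
            xyz, e = trial, e_trial
        if (stage + 1) % keep_every == 0 or stage == steps - 1:
            out.append(replace(
                start_pose,
                molecule=start_pose.molecule.with_coords(xyz.copy()),
                provenance=replace(start_pose.provenance, generator="torsional"),
                energy=float(e),
            ))
    return out
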