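"""Template harvesting, identity filtering, MCS computation and ranking.

Templates are holo complexes read from a local directory of PDB files.
Sequence identity to the target is computed locally by global alignment
(BLOSUM62, gap open 11 / extend 1); the retention threshold is inclusive
(identity >= 0.50 retained).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from rdkit import Chem
from rdkit.Chem import rdFMCS
from rdkit.Geometry import Point3D

from .structures import Atom, ContractError, Receptor, SmallMolecule

logger = logging.getLogger(__name__)

__all__ = [
    "TemplateComplex",
    "MCSResult",
    "compute_sequence_identity",
    "filter_templates",
    "extract_ligands",
    "compute_mcs",
    "rank_templates",
]

DEFAULT_MIN_IDENTITY = 0.50
MIN_LIGAND_HEAVY_ATOMS = 6

# waters, monoatomic ions and common cryo/buffer additives are never
# harvested as template ligands
EXCLUDED_RESIDUES = frozenset({
    "HOH", "DOD", "WAT", "GOL", "EDO", "PEG", "SO4", "PO4", "ACT", "DMS",
    "NA", "CL", "K", "MG", "CA", "ZN", "MN", "FE", "BR", "IOD", "CS", "LI",
    "NI", "CU", "CO", "CD", "HG",
})

# single-bond covalent radii (Angstrom), Cordero et al. values
COVALENT_RADII = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57, "P": 1.07,
    "S": 1.05, "Cl": 1.02, "Br": 1.20, "I": 1.39, "B": 0.84, "Se": 1.20,
    "Si": 1.11,
}
BOND_TOLERANCE = 0.45  # added to covalent-radius sum


@dataclass
class TemplateComplex:
    """A holo template: receptor plus one bound ligand with crystal coords."""

    source_id: str
    receptor: Receptor
    ligand: SmallMolecule
    identity: float = 0.0
    resolution: float | None = None

    def __post_init__(self):
        if not (0.0 <= self.identity <= 1.0):
            raise ContractError(f"identity {self.identity} outside [0, 1]")


@dataclass
class MCSResult:
    atom_map: list[tuple[int, int]]  # (target atom idx, template atom idx)
    n_atoms: int
    n_bonds: int
    coverage: float
    smarts: str = ""
    truncated: bool = False

    @property
    def target_atoms(self) -> list[int]:
        return [t for t, _ in self.atom_map]

    @property
    def template_atoms(self) -> list[int]:
        return [t for _, t in self.atom_map]


_ALIGNER = None


def _aligner() -> Align.PairwiseAligner:
    global _ALIGNER
    if _ALIGNER is None:
        a = Align.PairwiseAligner()
        a.mode = "global"
        a.substitution_matrix = substitution_matrices.load("BLOSUM62")
        a.open_gap_score = -11.0
        a.extend_gap_score = -1.0
        _ALIGNER = a
    return _ALIGNER


def align_sequences(seq_a: str, seq_b: str):
    """Best global alignment of two sequences (BLOSUM62, 11/1 gaps)."""
    if not seq_a or not seq_b:
        raise ContractError("empty sequence")
    aln = _aligner().align(seq_a.upper(), seq_b.upper())
    return aln[0]


def compute_sequence_identity(seq_a: str, seq_b: str) -> float:
    """Fraction of identical positions over alignment columns, excluding
    terminal gaps. Symmetric in its arguments."""
    aln = align_sequences(seq_a, seq_b)
    sa, sb = str(aln[0]), str(aln[1])
    # exclude terminal-gap columns: count from the first to the last column
    # where both rows carry a residue
    both = [i for i in range(len(sa)) if sa[i] != "-" and sb[i] != "-"]
    if not both:
        return 0.0
    start, end = both[0], both[-1] + 1
    columns = end - start
    if columns <= 0:
        return 0.0
    same = sum(1 for i in range(start, end) if sa[i] == sb[i] and sa[i] != "-")
    return same / columns


def filter_templates(templates: list[TemplateComplex],
                     min_identity: float = DEFAULT_MIN_IDENTITY) -> list[TemplateComplex]:
    """Retain templates with identity >= min_identity (inclusive boundary)."""
    return [t for t in templates if t.identity >= min_identity]


def _perceive_aromatic_rings(mol: Chem.RWMol, coords: np.ndarray) -> None:
    """Flag planar 5/6-rings of C/N/O/S with aromatic-range bond lengths."""
    ri = mol.GetRingInfo()
    for ring in ri.AtomRings():
        if len(ring) not in (5, 6):
            continue
        if any(mol.GetAtomWithIdx(i).GetSymbol() not in ("C", "N", "O", "S")
               for i in ring):
            continue
        pts = coords[list(ring)]
        centered = pts - pts.mean(axis=0)
        # planarity: smallest singular value = RMS out-of-plane extent
        sv = np.linalg.svd(centered, compute_uv=False)
        if sv[-1] / np.sqrt(len(ring)) > 0.12:
            continue
        ok = True
        n = len(ring)
        for k in range(n):
            i, j = ring[k], ring[(k + 1) % n]
            d = float(np.linalg.norm(coords[i] - coords[j]))
            if not (1.28 <= d <= 1.46):
                ok = False
                break
        if not ok:
            continue
        for i in ring:
            mol.GetAtomWithIdx(i).SetIsAromatic(True)
        for k in range(n):
            b = mol.GetBondBetweenAtoms(ring[k], ring[(k + 1) % n])
            b.SetBondType(Chem.BondType.AROMATIC)
            b.SetIsAromatic(True)


def _mol_from_hetero_atoms(atoms: list[Atom], name: str) -> SmallMolecule | None:
    coords = np.array([a.xyz for a in atoms], dtype=float)
    rw = Chem.RWMol()
    for a in atoms:
        rd = Chem.Atom(a.element)
        rd.SetNoImplicit(False)
        rw.AddAtom(rd)
    n = len(atoms)
    for i in range(n):
        ri = COVALENT_RADII.get(atoms[i].element, 0.77)
        for j in range(i + 1, n):
            rj = COVALENT_RADII.get(atoms[j].element, 0.77)
            d = float(np.linalg.norm(coords[i] - coords[j]))
            if d <= ri + rj + BOND_TOLERANCE and d > 0.4:
                rw.AddBond(i, j, Chem.BondType.SINGLE)
    Chem.FastFindRings(rw)
    _perceive_aromatic_rings(rw, coords)
    conf = Chem.Conformer(n)
    for i, p in enumerate(coords):
        conf.SetAtomPosition(i, Point3D(*map(float, p)))
    rw.AddConformer(conf)
    mol = rw.GetMol()
    try:
        Chem.SanitizeMol(mol)
    except Exception as exc:  # impossible valence etc. -> skip this ligand
        warnings.warn(f"skipping hetero residue {name}: {exc}")
        return None
    return SmallMolecule(mol, name)


def extract_ligands(structure: Receptor) -> list[SmallMolecule]:
    """Harvest one molecule per hetero residue instance.

    Bonds are perceived from interatomic distances (covalent-radius sum
    plus 0.45 Angstrom); aromatic rings are assigned from planarity and
    bond-length geometry.  Waters, ions, cryo/buffer additives and
    residues below the 6-heavy-atom floor are excluded.
    """
    residues: dict[tuple, list[Atom]] = {}
    order: list[tuple] = []
    for a in structure.hetero_atoms:
        key = a.residue_key()
        if key not in residues:
            residues[key] = []
            order.append(key)
        residues[key].append(a)
    ligands: list[SmallMolecule] = []
    for key in order:
        chain, res_seq, i_code, res_name = key
        if res_name.upper() in EXCLUDED_RESIDUES:
            continue
        atoms = residues[key]
        if len(atoms) < MIN_LIGAND_HEAVY_ATOMS:
            continue
        name = f"{res_name}_{chain}{res_seq}{i_code}"
        mol = _mol_from_hetero_atoms(atoms, name)
        if mol is not None:
            ligands.append(mol)
    return ligands


def compute_mcs(target: SmallMolecule, template_ligand: SmallMolecule,
                timeout_s: float = 10.0) -> MCSResult:
    """Largest connected common substructure under element equality,
    exact bond-order compatibility and ring-bond-matches-ring-bond."""
    t, l = target.rdmol, template_ligand.rdmol
    if t.GetNumHeavyAtoms() < 1 or l.GetNumHeavyAtoms() < 1:
        raise ContractError("both molecules need at least one heavy atom")
    res = rdFMCS.FindMCS(
        [t, l],
        maximizeBonds=False,
        atomCompare=rdFMCS.AtomCompare.CompareElements,
        bondCompare=rdFMCS.BondCompare.CompareOrderExact,
        ringMatchesRingOnly=True,
        timeout=max(1, int(round(timeout_s))),
    )
    n_target = t.GetNumHeavyAtoms()
    if res.numAtoms < 1 or not res.smartsString:
        # fall back to a best single-atom match on a shared element
        return _single_atom_mcs(t, l)
    pat = Chem.MolFromSmarts(res.smartsString)
    tm = t.GetSubstructMatch(pat)
    lm = l.GetSubstructMatch(pat)
    if not tm or not lm:
        return _single_atom_mcs(t, l)
    atom_map = sorted(zip(tm, lm))
    return MCSResult(
        atom_map=[(int(a), int(b)) for a, b in atom_map],
        n_atoms=int(res.numAtoms),
        n_bonds=int(res.numBonds),
        coverage=res.numAtoms / n_target,
        smarts=res.smartsString,
        truncated=bool(res.canceled),
    )


def _single_atom_mcs(t: Chem.Mol, l: Chem.Mol) -> MCSResult:
    # element AND ring-flag equality, consistent with ringMatchesRingOnly
    t_keys = {}
    for a in t.GetAtoms():
        t_keys.setdefault((a.GetSymbol(), a.IsInRing()), a.GetIdx())
    for a in l.GetAtoms():
        key = (a.GetSymbol(), a.IsInRing())
        if key in t_keys:
            return MCSResult(
                atom_map=[(t_keys[key], a.GetIdx())],
                n_atoms=1, n_bonds=0,
                coverage=1.0 / t.GetNumHeavyAtoms(),
                smarts=f"[#{a.GetAtomicNum()}]",
            )
    return MCSResult(atom_map=[], n_atoms=0, n_bonds=0, coverage=0.0)


def rank_templates(target: SmallMolecule, templates: list[TemplateComplex],
                   timeout_s: float = 10.0) -> list[tuple[TemplateComplex, MCSResult]]:
    """Order templates by descending MCS coverage of the target ligand.

    Ties break by higher identity, then smaller resolution, then
    lexicographic source id; fully deterministic.
    """
    scored = []
    for t in templates:
        mcs = compute_mcs(target, t.ligand, timeout_s=timeout_s)
        scored.append((t, mcs))
    scored.sort(key=lambda tm: (
        -tm[1].coverage,
        -tm[0].identity,
        tm[0].resolution if tm[0].resolution is not None else float("inf"),
        tm[0].source_id,
    ))
    return scored
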