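"""Foundational molecular types and PDB/SDF/SMILES input-output.

Coordinates are Angstrom throughout; receptors are heavy-atom only on
input (hydrogens discarded), ligands are heavy-atom graphs with implicit
hydrogen counts recorded on each atom.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Geometry import Point3D

logger = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "Receptor",
    "SmallMolecule",
    "FormatError",
    "ContractError",
    "read_receptor",
    "parse_small_molecule",
    "write_poses",
    "read_poses",
    "receptor_to_pdb",
]


class FormatError(ValueError):
    """Raised when an input file cannot be parsed."""


class ContractError(ValueError):
    """Raised when an operation precondition is violated."""


BACKBONE_NAMES = frozenset({"N", "CA", "C", "O"})

# 3-letter -> 1-letter for the 20 standard amino acids.
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


@dataclass
class Atom:
    element: str
    name: str
    res_name: str
    res_seq: int
    i_code: str
    chain: str
    xyz: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""
    is_backbone: bool = False
    is_hetero: bool = False

    def residue_key(self) -> tuple[str, int, str, str]:
        return (self.chain, self.res_seq, self.i_code, self.res_name)


@dataclass
class Receptor:
    """Atomic model of a protein with per-chain one-letter sequences."""

    atoms: list[Atom]
    chain_sequences: dict[str, str] = field(default_factory=dict)

    @property
    def polymer_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hetero]

    @property
    def hetero_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.is_hetero]

    def heavy_coords(self, polymer_only: bool = True) -> np.ndarray:
        atoms = self.polymer_atoms if polymer_only else self.atoms
        if not atoms:
            return np.zeros((0, 3))
        return np.array([a.xyz for a in atoms], dtype=float)

    def backbone_mask(self) -> np.ndarray:
        return np.array([a.is_backbone for a in self.polymer_atoms], dtype=bool)

    def ca_atoms(self, chain: str | None = None) -> list[Atom]:
        out = []
        for a in self.polymer_atoms:
            if a.name == "CA" and (chain is None or a.chain == chain):
                out.append(a)
        return out

    def longest_chain(self) -> str:
        if not self.chain_sequences:
            raise ContractError("receptor has no polymer chains")
        return max(self.chain_sequences, key=lambda c: (len(self.chain_sequences[c]), c))

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Receptor":
        atoms = []
        for a in self.atoms:
            b = Atom(a.element, a.name, a.res_name, a.res_seq, a.i_code, a.chain,
                     rotation @ a.xyz + translation, a.occupancy, a.altloc,
                     a.is_backbone, a.is_hetero)
            atoms.append(b)
        return Receptor(atoms, dict(self.chain_sequences))


@dataclass
class SmallMolecule:
    """Molecular graph with zero or more 3D conformers (wraps an RDKit Mol).

    The wrapped molecule is a heavy-atom graph; hydrogens are implicit.
    """

    rdmol: Chem.Mol
    name: str = ""

    @property
    def num_heavy_atoms(self) -> int:
        return self.rdmol.GetNumHeavyAtoms()

    @property
    def num_conformers(self) -> int:
        return self.rdmol.GetNumConformers()

    @property
    def smiles(self) -> str:
        return Chem.MolToSmiles(self.rdmol)

    def coords(self, conf_id: int = 0) -> np.ndarray:
        if self.rdmol.GetNumConformers() == 0:
            raise ContractError(f"molecule {self.name!r} has no conformer")
        return np.array(self.rdmol.GetConformer(conf_id).GetPositions(), dtype=float)

    def with_coords(self, xyz: np.ndarray, name: str | None = None) -> "SmallMolecule":
        """Copy of this molecule carrying exactly one conformer at *xyz*."""
        xyz = np.asarray(xyz, dtype=float)
        if xyz.shape != (self.rdmol.GetNumAtoms(), 3):
            raise ContractError(
                f"coordinate shape {xyz.shape} does not match atom count "
                f"{self.rdmol.GetNumAtoms()}")
        mol = Chem.Mol(self.rdmol)
        mol.RemoveAllConformers()
        conf = Chem.Conformer(mol.GetNumAtoms())
        for i, p in enumerate(xyz):
            conf.SetAtomPosition(i, Point3D(*map(float, p)))
        mol.AddConformer(conf, assignId=True)
        return SmallMolecule(mol, self.name if name is None else name)

    def copy(self) -> "SmallMolecule":
        return SmallMolecule(Chem.Mol(self.rdmol), self.name)


def _parse_pdb_atom_line(line: str) -> Atom | None:
    try:
        name = line[12:16].strip()
        altloc = line[16].strip()
        res_name = line[17:20].strip()
        chain = line[21].strip() or "A"
        res_seq = int(line[22:26])
        i_code = line[26].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        occ_s = line[54:60].strip()
        occ = float(occ_s) if occ_s else 1.0
        element = line[76:78].strip() if len(line) >= 78 else ""
    except (ValueError, IndexError) as exc:
        raise FormatError(f"unparsable PDB record: {line.rstrip()!r}") from exc
    if not element:
        # fall back to the atom-name convention (columns 13-14)
        element = "".join(c for c in line[12:14] if c.isalpha())
    element = element.strip().capitalize()
    if element in ("H", "D"):
        return None
    xyz = np.array([x, y, z], dtype=float)
    if not np.all(np.isfinite(xyz)):
        raise FormatError(f"non-finite coordinates in record: {line.rstrip()!r}")
    is_het = line.startswith("HETATM")
    return Atom(element, name, res_name, res_seq, i_code, chain, xyz,
                occ, altloc, is_backbone=False, is_hetero=is_het)


def read_receptor(pdb_text: str, altloc_policy: str = "highest-occupancy") -> Receptor:
    """Parse PDB-format text into a :class:`Receptor`.

    Hetero records are kept on the receptor (flagged ``is_hetero``) so that
    template ligands can be harvested later.  Hydrogens are dropped.
    Alternate locations are resolved per *altloc_policy*:
    ``highest-occupancy`` (ties broken by alphabetic tag) or ``keep-first``.
    """
    if altloc_policy not in ("highest-occupancy", "keep-first"):
        raise ContractError(f"unknown altloc policy {altloc_policy!r}")
    raw: list[Atom] = []
    for line in pdb_text.splitlines():
        if line.startswith(("ATOM  ", "HETATM")):
            atom = _parse_pdb_atom_line(line)
            if atom is not None:
                raw.append(atom)
        elif line.startswith("ENDMDL"):
            break  # first NMR model only
    if not raw:
        raise FormatError("no ATOM or HETATM records found")

    # resolve altlocs within (chain, residue, atom name) groups
    groups: dict[tuple, list[Atom]] = {}
    order: list[tuple] = []
    for a in raw:
        key = (a.chain, a.res_seq, a.i_code, a.res_name, a.name)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(a)
    atoms: list[Atom] = []
    for key in order:
        cands = groups[key]
        if len(cands) == 1:
            chosen = cands[0]
        elif altloc_policy == "keep-first":
            chosen = cands[0]
        else:
            chosen = max(cands, key=lambda a: (a.occupancy, _neg_ord(a.altloc)))
        atoms.append(chosen)

    # polymer residues: anything that is not HETATM
    for a in atoms:
        if not a.is_hetero and a.name in BACKBONE_NAMES:
            a.is_backbone = True

    sequences: dict[str, str] = {}
    seen_res: set[tuple] = set()
    for a in atoms:
        if a.is_hetero:
            continue
        rkey = a.residue_key()
        if rkey in seen_res:
            continue
        seen_res.add(rkey)
        letter = THREE_TO_ONE.get(a.res_name)
        if letter is None:
            warnings.warn(f"unknown residue {a.res_name!r} mapped to 'X'")
            letter = "X"
        sequences[a.chain] = sequences.get(a.chain, "") + letter
    return Receptor(atoms, sequences)


def _neg_ord(tag: str) -> int:
    # used as a max() key so that for equal occupancy an alphabetically
    # earlier altloc tag wins
    return -ord(tag) if tag else 0


def receptor_to_pdb(receptor: Receptor) -> str:
    """Serialize a receptor (including hetero atoms) back to PDB text."""
    lines = []
    serial = 1
    for a in receptor.atoms:
        record = "HETATM" if a.is_hetero else "ATOM  "
        name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
        lines.append(
            f"{record}{serial:>5d} {name:<4s}{'':1s}{a.res_name:>3s} {a.chain:1s}"
            f"{a.res_seq:>4d}{a.i_code:1s}   "
            f"{a.xyz[0]:8.3f}{a.xyz[1]:8.3f}{a.xyz[2]:8.3f}"
            f"{a.occupancy:6.2f}{0.0:6.2f}          {a.element:>2s}"
        )
        serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


def parse_small_molecule(text: str, name: str = "") -> SmallMolecule:
    """Parse a SMILES string or an SDF/MOL block into a :class:`SmallMolecule`.

    SDF input retains its conformer; hydrogens are folded into implicit
    counts on the heavy atoms.
    """
    if not text or not text.strip():
        raise FormatError("empty molecule input")
    stripped = text.strip()
    if "\n" in text or "V2000" in text or "V3000" in text:
        mol = Chem.MolFromMolBlock(text, removeHs=True)
        if mol is None:
            raise FormatError("unparsable SDF/MOL block")
        if not name:
            name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
    else:
        mol = Chem.MolFromSmiles(stripped)
        if mol is None:
            raise FormatError(f"invalid SMILES: {stripped!r}")
    if mol.GetNumHeavyAtoms() < 1:
        raise FormatError("molecule has no heavy atoms")
    return SmallMolecule(mol, name)


_POSE_TAGS = (
    ("template_id", lambda p: p.provenance.template_id),
    ("pattern_id", lambda p: p.provenance.pattern_id),
    ("match_index", lambda p: p.provenance.match_index),
    ("generator", lambda p: p.provenance.generator),
    ("anchor_rmsd", lambda p: p.anchor_rmsd),
    ("clash", lambda p: int(p.clash)),
    ("energy", lambda p: p.energy),
    ("overlap", lambda p: p.overlap),
    ("predicted_rmsd", lambda p: p.predicted_rmsd),
)


def write_poses(poses, destination=None) -> str:
    """Write poses to SDF (V2000) text, one record per pose.

    Provenance and all scores are emitted as SDF data tags.  If
    *destination* is a path or file object the text is also written there.
    """
    buf = io.StringIO()
    writer = Chem.SDWriter(buf)
    writer.SetForceV3000(False)
    for i, pose in enumerate(poses):
        if pose.molecule.num_conformers != 1:
            raise ContractError(
                f"pose {i} has {pose.molecule.num_conformers} conformers; "
                "exactly one required")
        mol = Chem.Mol(pose.molecule.rdmol)
        mol.SetProp("_Name", pose.molecule.name or f"pose_{i}")
        for tag, getter in _POSE_TAGS:
            value = getter(pose)
            if value is None:
                continue
            if isinstance(value, float):
                mol.SetProp(tag, f"{value:.6f}")
            else:
                mol.SetProp(tag, str(value))
        for tag, value in getattr(pose, "extra_tags", lambda: {})().items():
            mol.SetProp(tag, str(value))
        writer.write(mol)
    writer.close()
    text = buf.getvalue()
    if destination is not None:
        if hasattr(destination, "write"):
            destination.write(text)
        else:
            with open(destination, "w") as fh:
                fh.write(text)
    return text


def read_poses(sdf_text: str) -> list[tuple[SmallMolecule, dict[str, str]]]:
    """Read back an SDF written by :func:`write_poses`.

    Returns (molecule, tags) per record; used for round-trip checks and
    the evaluation CLI.
    """
    supplier = Chem.SDMolSupplier()
    supplier.SetData(sdf_text, removeHs=True)
    out = []
    for mol in supplier:
        if mol is None:
            raise FormatError("unparsable SDF record")
        tags = {k: mol.GetProp(k) for k in mol.GetPropNames()}
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
        out.append((SmallMolecule(mol, name), tags))
    return out
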