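"""Pharmacophoric feature typing and conserved-site clustering.

Features are assigned from a documented SMARTS dictionary (overridable);
conserved sites are found by greedy density clustering of same-type
feature atoms pooled across the aligned template ensemble.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from .structures import ContractError, SmallMolecule

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureAtom",
    "ConservedSite",
    "FEATURE_SMARTS",
    "assign_features",
    "cluster_conserved",
    "sites_to_json",
]

DEFAULT_RADIUS = 1.5      # Angstrom
DEFAULT_MIN_SUPPORT = 2   # distinct ligands

# Default feature dictionary. An atom may carry several types; patterns
# are matched independently and the union of hits is kept.
FEATURE_SMARTS: dict[str, tuple[str, ...]] = {
    "donor": (
        "[N;!H0;!$([N-])]",
        "[O;!H0]",
        "[n;H1]",
    ),
    "acceptor": (
        "[OX2;!$(O=*)]",
        "[OX1]",
        "[O-]",
        "[o;+0;X2]",
        # sp3/sp2 N with a lone pair: exclude amide N, anilinic/aromatic N-H
        "[NX3;H0;!$(N[C,S,P]=[O,S,N]);!$(N~a)]",
        "[NX2;!$(N=[O])]",
        "[nX2;+0]",
    ),
    "aromatic": ("[a]",),
    "hydrophobic": (
        "[#6;!$([#6]~[#7,#8])]",
        "[#16;!$([#16]~[#7,#8])]",
        "[F,Cl,Br,I;!$([*]~[#7,#8])]",
    ),
    "cation": (
        "[+;!$([-])]",
        "[NX4]",
        "[NX3;H2,H1;!$(NC=O);!$(N~a);!$(N~[#7,#8])]",
        "N=C(-N)-N",  # guanidinium-like
    ),
    "anion": (
        "[$([OX1]=[CX3][OX1-,OX2H1]),$([OX1-,OX2H1][CX3]=[OX1])]",  # carboxylate
        "[$([OX1,OX1-]~[SX4](~[OX1,OX1-])~[OX1,OX1-])]",            # sulfonate/sulfate
        "[$([OX1,OX1-]~[PX4](~[OX1,OX1-]))]",                       # phosphonate/phosphate
        "[nX2r5;$(n1nnnc1),$(n1nncn1)]",                            # tetrazole
        "[-;!$([+])]",
    ),
}

_COMPILED: dict[str, tuple[Chem.Mol, ...]] | None = None


def _compiled() -> dict[str, tuple[Chem.Mol, ...]]:
    global _COMPILED
    if _COMPILED is None:
        _COMPILED = {
            ftype: tuple(Chem.MolFromSmarts(s) for s in patterns)
            for ftype, patterns in FEATURE_SMARTS.items()
        }
        for ftype, pats in _COMPILED.items():
            if any(p is None for p in pats):
                raise ValueError(f"invalid SMARTS in feature dictionary: {ftype}")
    return _COMPILED


@dataclass
class FeatureAtom:
    ligand_id: str
    atom_index: int
    feature_types: frozenset[str]
    xyz: np.ndarray

    def __post_init__(self):
        if not self.feature_types:
            raise ContractError("feature atom with empty type set")
        self.xyz = np.asarray(self.xyz, dtype=float)
        if not np.all(np.isfinite(self.xyz)):
            raise ContractError("non-finite feature coordinates")


@dataclass
class ConservedSite:
    feature_type: str
    centroid: np.ndarray
    members: list[FeatureAtom] = field(default_factory=list)

    @property
    def support(self) -> int:
        return len({m.ligand_id for m in self.members})


def assign_features(mol: SmallMolecule) -> list[FeatureAtom]:
    """Type each atom of a single-conformer molecule by the dictionary."""
    if mol.num_conformers < 1:
        raise ContractError("assign_features needs a conformer")
    rd = mol.rdmol
    coords = mol.coords()
    types_per_atom: dict[int, set[str]] = {}
    for ftype, patterns in _compiled().items():
        for pat in patterns:
            for match in rd.GetSubstructMatches(pat, uniquify=True):
                for idx in match:
                    # multi-atom patterns (e.g. guanidinium) type every
                    # matched heavy atom of the relevant element
                    if ftype in ("cation", "anion") and \
                            rd.GetAtomWithIdx(idx).GetSymbol() == "C":
                        continue
                    types_per_atom.setdefault(idx, set()).add(ftype)
    out = []
    for idx in sorted(types_per_atom):
        out.append(FeatureAtom(
            ligand_id=mol.name or "ligand",
            atom_index=idx,
            feature_types=frozenset(types_per_atom[idx]),
            xyz=coords[idx],
        ))
    return out


def cluster_conserved(features: list[FeatureAtom],
                      radius: float = DEFAULT_RADIUS,
                      min_support: int = DEFAULT_MIN_SUPPORT) -> list[ConservedSite]:
    """Greedy density clustering per feature type.

    Repeatedly seed at the unassigned atom with the most same-type
    neighbours within *radius* (ties: lowest ligand id, then atom index),
    absorb its neighbours, and recurse on the remainder.  Sites supported
    by fewer than *min_support* distinct ligands are discarded.
    """
    by_type: dict[str, list[FeatureAtom]] = {}
    for f in features:
        for t in sorted(f.feature_types):
            by_type.setdefault(t, []).append(f)
    sites: list[ConservedSite] = []
    for ftype in sorted(by_type):
        atoms = sorted(by_type[ftype], key=lambda f: (f.ligand_id, f.atom_index))
        coords = np.array([f.xyz for f in atoms])
        n = len(atoms)
        d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
        neighbours = d2 <= radius * radius
        unassigned = np.ones(n, dtype=bool)
        while unassigned.any():
            counts = (neighbours & unassigned[None, :]).sum(axis=1)
            counts[~unassigned] = -1
            seed = int(np.argmax(counts))  # argmax takes the first max -> tie-break
            member_idx = np.where(neighbours[seed] & unassigned)[0]
            centroid = coords[member_idx].mean(axis=0)
            # invariant: every member lies within the radius of the centroid;
            # atoms pulled outside by the averaging return to the pool
            close = np.linalg.norm(coords[member_idx] - centroid, axis=1) <= radius
            if not close[member_idx == seed]:
                member_idx = np.array([seed])
                centroid = coords[seed].copy()
            else:
                member_idx = member_idx[close]
                centroid = coords[member_idx].mean(axis=0)
                if np.linalg.norm(coords[member_idx] - centroid, axis=1).max() > radius:
                    member_idx = np.array([seed])
                    centroid = coords[seed].copy()
            members = [atoms[i] for i in member_idx]
            sites.append(ConservedSite(ftype, centroid, members))
            unassigned[member_idx] = False
    kept = [s for s in sites if s.support >= min_support]
    logger.info("conserved sites: %d candidates, %d with support >= %d",
                len(sites), len(kept), min_support)
    return kept


def sites_to_json(sites: list[ConservedSite]) -> str:
    """Audit report: type, centroid and support of each conserved site."""
    payload = [
        {
            "feature_type": s.feature_type,
            "centroid": [round(float(v), 4) for v in s.centroid],
            "support": s.support,
            "n_members": len(s.members),
        }
        for s in sites
    ]
    return json.dumps(payload, indent=2)
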