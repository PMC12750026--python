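"""Composite SMARTS anchor construction and matching onto the target ligand.

MCS atoms that overlap conserved pharmacophoric sites are expanded to
connected fragments of the template ligand, rendered as generalized
SMARTS components (joined with "." when disconnected) and matched onto
the target; each match fixes anchor-atom coordinates taken from the
template ligand in the target frame.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from .pharmacophore import ConservedSite
from .structures import ContractError, SmallMolecule
from .templates import MCSResult, TemplateComplex

logger = logging.getLogger(__name__)

__all__ = [
    "AnchorPattern",
    "AnchorMapping",
    "NoAnchorError",
    "NoMatchError",
    "build_pattern",
    "full_mcs_pattern",
    "match_pattern",
    "pattern_to_json",
    "pattern_from_json",
]

DEFAULT_SITE_RADIUS = 1.5
MIN_COMPONENT_ATOMS = 3
MAX_MATCHES = 32

HALOGENS = {"F", "Cl", "Br", "I"}


class NoAnchorError(RuntimeError):
    """No MCS atom overlaps a conserved site; caller falls back to plain MCS."""


class NoMatchError(RuntimeError):
    """The pattern does not match the target; caller tries the next template."""


@dataclass
class AnchorPattern:
    smarts: str                       # components joined with "."
    coordinates: np.ndarray           # (n_pattern_atoms, 3), template in target frame
    source_template_id: str
    conservation_score: float = 0.0
    component_sizes: tuple[int, ...] = ()

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        query = Chem.MolFromSmarts(self.smarts)
        if query is None:
            raise ContractError(f"invalid SMARTS: {self.smarts!r}")
        if query.GetNumAtoms() != len(self.coordinates):
            raise ContractError(
                f"pattern has {query.GetNumAtoms()} atoms but "
                f"{len(self.coordinates)} coordinates")
        self._query = query

    @property
    def query(self) -> Chem.Mol:
        return self._query


@dataclass
class AnchorMapping:
    pattern: AnchorPattern
    match_index: int
    target_atoms: tuple[int, ...]     # pattern-atom order

    @property
    def anchor_coords(self) -> np.ndarray:
        return self.pattern.coordinates

    def as_dict(self) -> dict[int, np.ndarray]:
        return {t: self.pattern.coordinates[i]
                for i, t in enumerate(self.target_atoms)}


def _atom_query_symbol(atom: Chem.Atom, charged_feature_atoms: set[int]) -> str:
    """Generalized SMARTS symbol for one template-ligand atom.

    Aromatic atoms keep element + aromaticity, halogens widen to the
    four-halogen class, sp3 carbons to tetravalent carbon; formal charge
    is kept only on atoms inside a charged (cation/anion) feature.
    """
    sym = atom.GetSymbol()
    idx = atom.GetIdx()
    charge = atom.GetFormalCharge()
    if atom.GetIsAromatic():
        body = sym.lower() if len(sym) == 1 else f"#{atom.GetAtomicNum()};a"
        if idx in charged_feature_atoms and charge:
            return f"[{body}{'+' if charge > 0 else '-'}]"
        return f"[{body}]"
    if sym in HALOGENS:
        return "[F,Cl,Br,I]"
    if sym == "C" and atom.GetHybridization() == Chem.HybridizationType.SP3:
        return "[CX4]"
    if idx in charged_feature_atoms and charge:
        return f"[{sym}{'+' if charge > 0 else '-'}]"
    return f"[#{atom.GetAtomicNum()}]"


def _fragment_smarts(mol: Chem.Mol, atom_ids: list[int],
                     charged_feature_atoms: set[int]) -> tuple[str, list[int]]:
    """Render one connected fragment as SMARTS; returns (smarts, atom order)."""
    symbols = [
        _atom_query_symbol(a, charged_feature_atoms) for a in mol.GetAtoms()
    ]
    smarts = Chem.MolFragmentToSmiles(
        mol, atomsToUse=atom_ids, atomSymbols=symbols,
        allBondsExplicit=True, canonical=False)
    order = list(mol.GetPropsAsDict(True, True)["_smilesAtomOutputOrder"])
    # MolFragmentToSmiles reports the order over the fragment atoms only
    order = [i for i in order if i in set(atom_ids)]
    return smarts, order


def build_pattern(mcs: MCSResult, sites: list[ConservedSite],
                  template: TemplateComplex,
                  ligand_in_target_frame: SmallMolecule | None = None,
                  site_radius: float = DEFAULT_SITE_RADIUS) -> AnchorPattern:
    """Build the composite anchor SMARTS for one template.

    MCS atoms whose template coordinates lie within *site_radius* of any
    conserved-site centroid seed the pattern; they are grouped into
    connected fragments of the template ligand graph, fragments below
    3 atoms are dropped, and the remaining fragments are rendered as
    SMARTS components joined with ".".
    """
    if not mcs.atom_map:
        raise ContractError("empty MCS")
    ligand = ligand_in_target_frame if ligand_in_target_frame is not None \
        else template.ligand
    mol = ligand.rdmol
    coords = ligand.coords()
    centroids = np.array([s.centroid for s in sites]) if sites else np.zeros((0, 3))

    mcs_template_atoms = [b for _, b in mcs.atom_map]
    near: list[int] = []
    support_of: dict[int, int] = {}
    for idx in mcs_template_atoms:
        if centroids.shape[0] == 0:
            continue
        dists = np.linalg.norm(centroids - coords[idx], axis=1)
        hit = np.where(dists <= site_radius)[0]
        if hit.size:
            near.append(idx)
            support_of[idx] = max(sites[h].support for h in hit)
    if not near:
        raise NoAnchorError("no MCS atom lies near a conserved site")

    fragments = _connected_fragments(mol, near)
    fragments = [f for f in fragments if len(f) >= MIN_COMPONENT_ATOMS]
    if not fragments:
        raise NoAnchorError("all near-site fragments are below the size floor")

    charged = _charged_feature_atoms(mol)
    parts, coord_rows, sizes = [], [], []
    for frag in sorted(fragments, key=lambda f: sorted(f)):
        smarts, order = _fragment_smarts(mol, sorted(frag), charged)
        parts.append(smarts)
        coord_rows.extend(coords[i] for i in order)
        sizes.append(len(order))
    score_atoms = [support_of.get(i, 0) for f in fragments for i in f]
    conservation = float(np.mean([s for s in score_atoms if s > 0] or [0.0]))
    pattern = AnchorPattern(
        smarts=".".join(parts),
        coordinates=np.array(coord_rows),
        source_template_id=template.source_id,
        conservation_score=conservation,
        component_sizes=tuple(sizes),
    )
    _check_self_match(pattern, ligand)
    return pattern


def full_mcs_pattern(mcs: MCSResult, template: TemplateComplex,
                     ligand_in_target_frame: SmallMolecule | None = None) -> AnchorPattern:
    """Fallback anchor covering the full MCS (no pharmacophore available)."""
    if not mcs.atom_map:
        raise ContractError("empty MCS")
    ligand = ligand_in_target_frame if ligand_in_target_frame is not None \
        else template.ligand
    mol = ligand.rdmol
    coords = ligand.coords()
    atoms = [b for _, b in mcs.atom_map]
    fragments = [f for f in _connected_fragments(mol, atoms)
                 if len(f) >= MIN_COMPONENT_ATOMS]
    if not fragments:
        raise NoAnchorError("MCS too small to anchor")
    charged = _charged_feature_atoms(mol)
    parts, coord_rows, sizes = [], [], []
    for frag in sorted(fragments, key=lambda f: sorted(f)):
        smarts, order = _fragment_smarts(mol, sorted(frag), charged)
        parts.append(smarts)
        coord_rows.extend(coords[i] for i in order)
        sizes.append(len(order))
    return AnchorPattern(
        smarts=".".join(parts),
        coordinates=np.array(coord_rows),
        source_template_id=template.source_id,
        conservation_score=0.0,
        component_sizes=tuple(sizes),
    )


def _connected_fragments(mol: Chem.Mol, atom_ids: list[int]) -> list[set[int]]:
    """Connected components of the subgraph induced on *atom_ids*."""
    selected = set(atom_ids)
    seen: set[int] = set()
    out: list[set[int]] = []
    for start in sorted(selected):
        if start in seen:
            continue
        comp = {start}
        stack = [start]
        while stack:
            i = stack.pop()
            for nb in mol.GetAtomWithIdx(i).GetNeighbors():
                j = nb.GetIdx()
                if j in selected and j not in comp:
                    comp.add(j)
                    stack.append(j)
        seen |= comp
        out.append(comp)
    return out


def _charged_feature_atoms(mol: Chem.Mol) -> set[int]:
    return {a.GetIdx() for a in mol.GetAtoms() if a.GetFormalCharge() != 0}


def _check_self_match(pattern: AnchorPattern, ligand: SmallMolecule) -> None:
    if not ligand.rdmol.GetSubstructMatch(pattern.query):
        logger.warning("pattern %r does not re-match its source template ligand",
                       pattern.smarts)


def match_pattern(pattern: AnchorPattern, target: SmallMolecule,
                  max_matches: int = MAX_MATCHES) -> list[AnchorMapping]:
    """Enumerate substructure matches of the pattern on the target ligand.

    Matches are deduplicated per pattern component: two matches are
    equivalent when each component covers the same target atom set
    (component-internal symmetry such as ring rotation collapses; distinct
    component-to-fragment assignments are kept).  The retained matches are
    ordered lexicographically on their sorted target indices and capped.
    """
    raw = target.rdmol.GetSubstructMatches(
        pattern.query, uniquify=False, maxMatches=100000)
    if not raw:
        raise NoMatchError(
            f"pattern from template {pattern.source_template_id} has no match")
    sizes = pattern.component_sizes or (pattern.query.GetNumAtoms(),)
    seen: set[tuple] = set()
    unique: list[tuple[int, ...]] = []
    for match in raw:
        key_parts = []
        off = 0
        for size in sizes:
            key_parts.append(frozenset(match[off:off + size]))
            off += size
        key = tuple(key_parts)
        if key in seen:
            continue
        seen.add(key)
        unique.append(tuple(int(i) for i in match))
    unique.sort(key=lambda m: tuple(sorted(m)))
    out = [AnchorMapping(pattern, i, m) for i, m in enumerate(unique[:max_matches])]
    return out


def pattern_to_json(pattern: AnchorPattern) -> str:
    return json.dumps({
        "smarts": pattern.smarts,
        "coordinates": [[round(float(v), 6) for v in row]
                        for row in pattern.coordinates],
        "source_template_id": pattern.source_template_id,
        "conservation_score": pattern.conservation_score,
        "component_sizes": list(pattern.component_sizes),
    }, indent=2)


def pattern_from_json(text: str) -> AnchorPattern:
    d = json.loads(text)
    return AnchorPattern(
        smarts=d["smarts"],
        coordinates=np.array(d["coordinates"], dtype=float),
        source_template_id=d.get("source_template_id", "user"),
        conservation_score=float(d.get("conservation_score", 0.0)),
        component_sizes=tuple(d.get("component_sizes", [])),
    )
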