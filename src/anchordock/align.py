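"""Receptor superposition and template-ensemble construction.

Superposition is a sequence-guided iterative Kabsch fit over CA atoms
with up to five outlier-rejection cycles (residual > 2.0 Angstrom
discarded), mirroring the behaviour of standard structure-alignment
commands at the contract level.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .structures import ContractError, Receptor, SmallMolecule
from .templates import MCSResult, TemplateComplex, align_sequences

logger = logging.getLogger(__name__)

__all__ = [
    "RigidTransform",
    "EnsembleMember",
    "TemplateEnsemble",
    "AlignmentError",
    "superpose",
    "build_ensemble",
]

REJECT_RESIDUAL = 2.0   # Angstrom
MAX_REJECT_CYCLES = 5
MIN_PAIRS = 3


class AlignmentError(RuntimeError):
    """Raised when two receptors cannot be superposed."""


@dataclass
class RigidTransform:
    rotation: np.ndarray      # 3x3, orthonormal, det +1
    translation: np.ndarray   # length-3, Angstrom

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        err = np.abs(self.rotation.T @ self.rotation - np.eye(3)).max()
        if err > 1e-6:
            raise ContractError(f"rotation not orthonormal (err {err:.2e})")
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-6:
            raise ContractError("rotation determinant is not +1")

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        return np.asarray(xyz, dtype=float) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: x -> self(other(x))."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> RigidTransform:
    """Least-squares rigid transform mapping *mobile* onto *reference*."""
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    cm, cr = mobile.mean(axis=0), reference.mean(axis=0)
    H = (mobile - cm).T @ (reference - cr)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = cr - R @ cm
    return RigidTransform(R, t)


def _ca_pairs(reference: Receptor, mobile: Receptor) -> tuple[np.ndarray, np.ndarray]:
    """CA coordinate pairs from a global alignment of the longest chains."""
    ref_chain = reference.longest_chain()
    mob_chain = mobile.longest_chain()
    ref_cas = reference.ca_atoms(ref_chain)
    mob_cas = mobile.ca_atoms(mob_chain)
    ref_seq = reference.chain_sequences[ref_chain]
    mob_seq = mobile.chain_sequences[mob_chain]
    # the sequence is derived per residue; CA lists must line up with it
    if len(ref_cas) != len(ref_seq) or len(mob_cas) != len(mob_seq):
        raise AlignmentError("chain sequence and CA atoms are inconsistent")
    aln = align_sequences(ref_seq, mob_seq)
    ref_xyz, mob_xyz = [], []
    ra, rb = aln.aligned
    for (a0, a1), (b0, b1) in zip(ra, rb):
        for off in range(a1 - a0):
            ref_xyz.append(ref_cas[a0 + off].xyz)
            mob_xyz.append(mob_cas[b0 + off].xyz)
    if len(ref_xyz) < MIN_PAIRS:
        raise AlignmentError(f"only {len(ref_xyz)} alignable CA pairs")
    return np.array(ref_xyz), np.array(mob_xyz)


def superpose(reference: Receptor, mobile: Receptor) -> tuple[RigidTransform, float, int]:
    """Superpose *mobile* onto *reference*; returns (transform, rmsd, n_pairs).

    The reported RMSD is over the CA pairs surviving outlier rejection.
    """
    if len(reference.ca_atoms()) < MIN_PAIRS or len(mobile.ca_atoms()) < MIN_PAIRS:
        raise AlignmentError("need at least 3 CA atoms on each structure")
    ref_xyz, mob_xyz = _ca_pairs(reference, mobile)
    keep = np.ones(len(ref_xyz), dtype=bool)
    transform = RigidTransform.identity()
    for _ in range(MAX_REJECT_CYCLES + 1):
        transform = kabsch(mob_xyz[keep], ref_xyz[keep])
        residuals = np.linalg.norm(transform.apply(mob_xyz) - ref_xyz, axis=1)
        bad = keep & (residuals > REJECT_RESIDUAL)
        if not bad.any():
            break
        if (keep.sum() - bad.sum()) < MIN_PAIRS:
            break
        keep &= ~bad
    residuals = np.linalg.norm(transform.apply(mob_xyz[keep]) - ref_xyz[keep], axis=1)
    rmsd = float(np.sqrt((residuals ** 2).mean()))
    n_pairs = int(keep.sum())
    if n_pairs < MIN_PAIRS:
        raise AlignmentError("fewer than 3 matched CA pairs survive")
    return transform, rmsd, n_pairs


@dataclass
class EnsembleMember:
    template: TemplateComplex
    mcs: MCSResult
    transform: RigidTransform
    rmsd: float
    n_pairs: int
    ligand_in_target_frame: SmallMolecule = None


@dataclass
class TemplateEnsemble:
    target: Receptor
    members: list[EnsembleMember] = field(default_factory=list)

    @property
    def pooled_ligands(self) -> list[SmallMolecule]:
        return [m.ligand_in_target_frame for m in self.members]

    def pooled_heavy_coords(self) -> np.ndarray:
        if not self.members:
            return np.zeros((0, 3))
        return np.vstack([m.ligand_in_target_frame.coords() for m in self.members])


def build_ensemble(target: Receptor,
                   ranked: list[tuple[TemplateComplex, MCSResult]]) -> TemplateEnsemble:
    """Superpose each ranked template onto the target and pool its ligand
    in the target frame; templates that fail to align are dropped."""
    if not ranked:
        raise ContractError("ranked template list is empty")
    ensemble = TemplateEnsemble(target)
    for template, mcs in ranked:
        try:
            transform, rmsd, n_pairs = superpose(target, template.receptor)
        except AlignmentError as exc:
            warnings.warn(f"template {template.source_id}: alignment failed ({exc})")
            continue
        moved = template.ligand.with_coords(transform.apply(template.ligand.coords()))
        ensemble.members.append(EnsembleMember(
            template=template, mcs=mcs, transform=transform,
            rmsd=rmsd, n_pairs=n_pairs, ligand_in_target_frame=moved))
        logger.info("aligned template %s: rmsd %.3f A over %d CA pairs",
                    template.source_id, rmsd, n_pairs)
    if not ensemble.members:
        raise AlignmentError("no template could be aligned to the target")
    return ensemble
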