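"""Simplified molecular-mechanics engine used for restrained minimization.

Terms: harmonic bonds and angles, cosine torsions, Lennard-Jones,
Coulomb with a distance-dependent dielectric, and harmonic positional
tethers.  Energies are in internal units comparable only within a run.
The minimizer is a steepest-descent with backtracking line search, so
energy never increases; a pluggable engine with the same contract can be
substituted for a full force-field setup.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

logger = logging.getLogger(__name__)

__all__ = [
    "EnergyModel", "HarmonicBonds", "HarmonicAngles", "CosineTorsions",
    "LennardJones", "CoulombDD", "Tethers", "minimize",
    "build_ligand_terms", "ligand_receptor_lj", "LJ_PARAMS",
]

COULOMB_CONST = 332.06  # kcal/mol * A / e^2

# per-element (sigma Angstrom, epsilon kcal/mol)
LJ_PARAMS = {
    "C": (3.40, 0.09), "N": (3.25, 0.17), "O": (2.96, 0.21),
    "S": (3.56, 0.25), "P": (3.74, 0.20), "F": (3.12, 0.06),
    "Cl": (3.47, 0.27), "Br": (3.60, 0.32), "I": (3.83, 0.40),
    "H": (2.50, 0.02),
}
LJ_DEFAULT = (3.40, 0.10)

K_BOND = 300.0    # kcal/mol/A^2
K_ANGLE = 60.0    # kcal/mol/rad^2
V_TORSION_SP3 = 0.3
V_TORSION_CONJ = 3.0


class Term:
    def energy_grad(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        raise NotImplementedError


@dataclass
class HarmonicBonds(Term):
    pairs: np.ndarray    # (n, 2) int
    r0: np.ndarray
    k: float = K_BOND

    def energy_grad(self, x):
        g = np.zeros_like(x)
        if len(self.pairs) == 0:
            return 0.0, g
        d = x[self.pairs[:, 0]] - x[self.pairs[:, 1]]
        r = np.linalg.norm(d, axis=1)
        dr = r - self.r0
        e = float(np.sum(self.k * dr ** 2))
        f = (2.0 * self.k * dr / np.maximum(r, 1e-12))[:, None] * d
        np.add.at(g, self.pairs[:, 0], f)
        np.add.at(g, self.pairs[:, 1], -f)
        return e, g


@dataclass
class HarmonicAngles(Term):
    triples: np.ndarray  # (n, 3) int: i - j - k with j the apex
    theta0: np.ndarray
    k: float = K_ANGLE

    def energy_grad(self, x):
        g = np.zeros_like(x)
        if len(self.triples) == 0:
            return 0.0, g
        i, j, kk = self.triples.T
        u = x[i] - x[j]
        v = x[kk] - x[j]
        nu = np.linalg.norm(u, axis=1)
        nv = np.linalg.norm(v, axis=1)
        uh = u / nu[:, None]
        vh = v / nv[:, None]
        cos = np.clip((uh * vh).sum(1), -1.0, 1.0)
        theta = np.arccos(cos)
        sin = np.sqrt(np.maximum(1.0 - cos ** 2, 1e-10))
        dth = theta - self.theta0
        e = float(np.sum(self.k * dth ** 2))
        pref = 2.0 * self.k * dth
        ga = (pref / (nu * sin))[:, None] * (uh * cos[:, None] - vh)
        gc = (pref / (nv * sin))[:, None] * (vh * cos[:, None] - uh)
        np.add.at(g, i, ga)
        np.add.at(g, kk, gc)
        np.add.at(g, j, -(ga + gc))
        return e, g


@dataclass
class CosineTorsions(Term):
    quads: np.ndarray   # (n, 4) int
    n_fold: np.ndarray  # periodicity
    v: np.ndarray       # barrier height
    gamma: np.ndarray   # phase

    def energy_grad(self, x):
        g = np.zeros_like(x)
        if len(self.quads) == 0:
            return 0.0, g
        a, b, c, d = self.quads.T
        b1 = x[b] - x[a]
        b2 = x[c] - x[b]
        b3 = x[d] - x[c]
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        nb2 = np.linalg.norm(b2, axis=1)
        m = np.cross(n1, b2 / nb2[:, None])
        xx = (n1 * n2).sum(1)
        yy = (m * n2).sum(1)
        phi = np.arctan2(yy, xx)
        e = float(np.sum(0.5 * self.v * (1.0 + np.cos(self.n_fold * phi - self.gamma))))
        dEdphi = -0.5 * self.v * self.n_fold * np.sin(self.n_fold * phi - self.gamma)
        n1sq = np.maximum((n1 ** 2).sum(1), 1e-12)
        n2sq = np.maximum((n2 ** 2).sum(1), 1e-12)
        # dphi/dr for the atan2(m.n2, n1.n2) convention, validated
        # against numerical differentiation
        ga = (dEdphi * nb2 / n1sq)[:, None] * n1
        gd = (-dEdphi * nb2 / n2sq)[:, None] * n2
        s12 = ((b1 * b2).sum(1) / nb2 ** 2)[:, None]
        s32 = ((b3 * b2).sum(1) / nb2 ** 2)[:, None]
        gb = -(1.0 + s12) * ga + s32 * gd
        gc = -(ga + gb + gd)
        np.add.at(g, a, ga)
        np.add.at(g, b, gb)
        np.add.at(g, c, gc)
        np.add.at(g, d, gd)
        return e, g


@dataclass
class LennardJones(Term):
    pairs: np.ndarray
    sigma: np.ndarray
    eps: np.ndarray
    scale: np.ndarray | None = None

    def energy_grad(self, x):
        g = np.zeros_like(x)
        if len(self.pairs) == 0:
            return 0.0, g
        d = x[self.pairs[:, 0]] - x[self.pairs[:, 1]]
        r = np.maximum(np.linalg.norm(d, axis=1), 0.3)
        sr6 = (self.sigma / r) ** 6
        s = self.scale if self.scale is not None else 1.0
        e_pair = 4.0 * self.eps * (sr6 ** 2 - sr6) * s
        e = float(np.sum(e_pair))
        dEdr = 4.0 * self.eps * (-12.0 * sr6 ** 2 + 6.0 * sr6) / r * s
        f = (dEdr / r)[:, None] * d
        np.add.at(g, self.pairs[:, 0], f)
        np.add.at(g, self.pairs[:, 1], -f)
        return e, g


@dataclass
class CoulombDD(Term):
    """Coulomb with distance-dependent dielectric eps(r) = 4r."""

    pairs: np.ndarray
    qq: np.ndarray      # q_i * q_j
    scale: np.ndarray | None = None

    def energy_grad(self, x):
        g = np.zeros_like(x)
        if len(self.pairs) == 0:
            return 0.0, g
        d = x[self.pairs[:, 0]] - x[self.pairs[:, 1]]
        r = np.maximum(np.linalg.norm(d, axis=1), 0.3)
        s = self.scale if self.scale is not None else 1.0
        e_pair = COULOMB_CONST * self.qq / (4.0 * r ** 2) * s
        e = float(np.sum(e_pair))
        dEdr = -2.0 * COULOMB_CONST * self.qq / (4.0 * r ** 3) * s
        f = (dEdr / r)[:, None] * d
        np.add.at(g, self.pairs[:, 0], f)
        np.add.at(g, self.pairs[:, 1], -f)
        return e, g


@dataclass
class Tethers(Term):
    indices: np.ndarray
    ref: np.ndarray
    k: float

    def energy_grad(self, x):
        g = np.zeros_like(x)
        if len(self.indices) == 0:
            return 0.0, g
        d = x[self.indices] - self.ref
        e = float(np.sum(self.k * d ** 2))
        g[self.indices] = 2.0 * self.k * d
        return e, g


@dataclass
class EnergyModel:
    terms: list[Term]
    frozen: np.ndarray | None = None   # boolean mask over atoms; True = immobile

    def energy_grad(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        e_tot = 0.0
        g_tot = np.zeros_like(x)
        for term in self.terms:
            e, g = term.energy_grad(x)
            e_tot += e
            g_tot += g
        if self.frozen is not None:
            g_tot[self.frozen] = 0.0
        return e_tot, g_tot

    def energy(self, x: np.ndarray) -> float:
        return self.energy_grad(x)[0]


def minimize(model: EnergyModel, x0: np.ndarray, steps: int,
             grad_tol: float = 1e-4) -> tuple[np.ndarray, float, int]:
    """Steepest descent with backtracking; returns (x, energy, iterations).

    Runs exactly *steps* iterations unless the max gradient component
    drops below *grad_tol* first.  Energy is non-increasing; frozen atoms
    never move.
    """
    x = np.array(x0, dtype=float)
    e, g = model.energy_grad(x)
    if not np.isfinite(e):
        raise ValueError("non-finite energy at input coordinates")
    iterations = 0
    step = 1e-3
    for _ in range(steps):
        gmax = np.abs(g).max() if g.size else 0.0
        if gmax < grad_tol:
            break
        iterations += 1
        moved = False
        trial_step = step
        for _ in range(40):
            x_new = x - trial_step * g
            e_new, g_new = model.energy_grad(x_new)
            if np.isfinite(e_new) and e_new <= e:
                x, e, g = x_new, e_new, g_new
                step = trial_step * 1.5
                moved = True
                break
            trial_step *= 0.5
        if not moved:
            step = max(step * 0.5, 1e-10)
    return x, e, iterations


# ---------------------------------------------------------------------------
# parameterization of a heavy-atom ligand graph

def _theta0(atom: Chem.Atom) -> float:
    hyb = atom.GetHybridization()
    if atom.GetIsAromatic() or hyb == Chem.HybridizationType.SP2:
        return np.deg2rad(120.0)
    if hyb == Chem.HybridizationType.SP:
        return np.deg2rad(179.9)
    return np.deg2rad(109.47)


_BOND_ORDER_FACTOR = {
    Chem.BondType.SINGLE: 1.0,
    Chem.BondType.AROMATIC: 0.92,
    Chem.BondType.DOUBLE: 0.87,
    Chem.BondType.TRIPLE: 0.78,
}

_RCOV = {"C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05, "P": 1.07, "F": 0.57,
         "Cl": 1.02, "Br": 1.20, "I": 1.39, "B": 0.84, "Se": 1.20}


def gasteiger_heavy_charges(mol: Chem.Mol) -> np.ndarray:
    m = Chem.Mol(mol)
    try:
        from rdkit.Chem import rdPartialCharges
        rdPartialCharges.ComputeGasteigerCharges(m)
        q = []
        for a in m.GetAtoms():
            qa = float(a.GetProp("_GasteigerCharge"))
            if a.HasProp("_GasteigerHCharge"):
                qa += float(a.GetProp("_GasteigerHCharge"))
            q.append(qa if np.isfinite(qa) else 0.0)
        return np.array(q)
    except Exception:
        return np.zeros(mol.GetNumAtoms())


def build_ligand_terms(mol: Chem.Mol) -> list[Term]:
    """Bonded + intramolecular nonbonded terms for a heavy-atom molecule."""
    terms: list[Term] = []
    pairs, r0 = [], []
    for b in mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        ri = _RCOV.get(b.GetBeginAtom().GetSymbol(), 0.77)
        rj = _RCOV.get(b.GetEndAtom().GetSymbol(), 0.77)
        fac = _BOND_ORDER_FACTOR.get(b.GetBondType(), 1.0)
        pairs.append((i, j))
        r0.append((ri + rj) * fac)
    if pairs:
        terms.append(HarmonicBonds(np.array(pairs), np.array(r0)))

    triples, theta0 = [], []
    for a in mol.GetAtoms():
        nbrs = [n.GetIdx() for n in a.GetNeighbors()]
        for x in range(len(nbrs)):
            for y in range(x + 1, len(nbrs)):
                triples.append((nbrs[x], a.GetIdx(), nbrs[y]))
                theta0.append(_theta0(a))
    if triples:
        terms.append(HarmonicAngles(np.array(triples), np.array(theta0)))

    quads, nf, v, gamma = [], [], [], []
    for b in mol.GetBonds():
        j, k = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        aj, ak = mol.GetAtomWithIdx(j), mol.GetAtomWithIdx(k)
        js = [n.GetIdx() for n in aj.GetNeighbors() if n.GetIdx() != k]
        ks = [n.GetIdx() for n in ak.GetNeighbors() if n.GetIdx() != j]
        if not js or not ks:
            continue
        conj = b.GetIsAromatic() or b.GetBondType() in (
            Chem.BondType.DOUBLE, Chem.BondType.AROMATIC) or b.GetIsConjugated()
        for i in js:
            for l in ks:
                if i == l:
                    continue
                quads.append((i, j, k, l))
                if conj:
                    nf.append(2.0)
                    v.append(V_TORSION_CONJ)
                    gamma.append(np.pi)
                else:
                    nf.append(3.0)
                    v.append(V_TORSION_SP3)
                    gamma.append(0.0)
    if quads:
        terms.append(CosineTorsions(np.array(quads), np.array(nf),
                                    np.array(v), np.array(gamma)))

    # intramolecular nonbonded: graph distance >= 3, 1-4 scaled 0.5
    n = mol.GetNumAtoms()
    dist = Chem.GetDistanceMatrix(mol)
    q = gasteiger_heavy_charges(mol)
    nb_pairs, sig, eps, scale, qq = [], [], [], [], []
    for i in range(n):
        si, ei = LJ_PARAMS.get(mol.GetAtomWithIdx(i).GetSymbol(), LJ_DEFAULT)
        for j in range(i + 1, n):
            if dist[i, j] < 3:
                continue
            sj, ej = LJ_PARAMS.get(mol.GetAtomWithIdx(j).GetSymbol(), LJ_DEFAULT)
            nb_pairs.append((i, j))
            sig.append(0.5 * (si + sj))
            eps.append(np.sqrt(ei * ej))
            scale.append(0.5 if dist[i, j] == 3 else 1.0)
            qq.append(q[i] * q[j])
    if nb_pairs:
        nb_pairs = np.array(nb_pairs)
        scale = np.array(scale)
        terms.append(LennardJones(nb_pairs, np.array(sig), np.array(eps), scale))
        terms.append(CoulombDD(nb_pairs, np.array(qq), scale))
    return terms


def ligand_receptor_lj(ligand_elems: list[str], ligand_offset: int,
                       receptor_elems: list[str], receptor_offset: int) -> LennardJones:
    """LJ between every ligand heavy atom and every receptor heavy atom.

    Atom indices refer to a combined coordinate array; receptor-receptor
    interactions are deliberately excluded (receptor topology is unknown
    to the generic engine).
    """
    pairs, sig, eps = [], [], []
    for i, ei in enumerate(ligand_elems):
        si, epi = LJ_PARAMS.get(ei, LJ_DEFAULT)
        for j, ej in enumerate(receptor_elems):
            sj, epj = LJ_PARAMS.get(ej, LJ_DEFAULT)
            pairs.append((ligand_offset + i, receptor_offset + j))
            sig.append(0.5 * (si + sj))
            eps.append(np.sqrt(epi * epj))
    return LennardJones(np.array(pairs, dtype=int).reshape(-1, 2),
                        np.array(sig), np.array(eps))
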