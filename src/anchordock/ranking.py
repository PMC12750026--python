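"""Pose clustering, template-ensemble overlap, RMSD-confidence regression
and final composite prioritization.

The confidence model is an invariant-feature regressor honouring the
pose+receptor -> nonnegative Angstrom scalar contract; its features are
rigid-motion invariant by construction.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdMolDescriptors
from scipy.spatial import cKDTree
from scipy.stats import spearmanr

from .align import TemplateEnsemble
from .sampling import Pose
from .structures import ContractError, Receptor

logger = logging.getLogger(__name__)

__all__ = [
    "PoseCluster", "ConfidenceModel", "RankedPrediction",
    "symmetry_rmsd", "butina_cluster", "overlap_score",
    "pose_features", "FEATURE_NAMES",
    "fit_confidence", "predict_confidence", "rank",
]

BUTINA_CUTOFF = 0.5       # Angstrom, inclusive neighbour rule
OVERLAP_RADIUS = 1.5      # Angstrom
AUTOMORPHISM_CAP = 10_000
CONTACT_SHELL = 4.0       # Angstrom


def _automorphisms(mol: Chem.Mol) -> list[tuple[int, ...]]:
    matches = mol.GetSubstructMatches(
        mol, uniquify=False, useChirality=False, maxMatches=AUTOMORPHISM_CAP + 1)
    if len(matches) > AUTOMORPHISM_CAP:
        warnings.warn("automorphism count exceeds cap; using identity mapping")
        return [tuple(range(mol.GetNumAtoms()))]
    return list(matches) or [tuple(range(mol.GetNumAtoms()))]


def symmetry_rmsd(a: Pose, b: Pose) -> float:
    """Heavy-atom RMSD minimized over graph automorphisms, in place
    (no refitting)."""
    ma, mb = a.molecule.rdmol, b.molecule.rdmol
    if Chem.MolToSmiles(ma) != Chem.MolToSmiles(mb):
        raise ContractError("poses have different molecular graphs")
    xa, xb = a.coords(), b.coords()
    if ma.GetNumAtoms() != mb.GetNumAtoms():
        raise ContractError("atom count mismatch")
    best = np.inf
    for perm in _automorphisms(ma):
        d = xa[list(perm)] - xb
        rmsd = np.sqrt((d ** 2).sum(axis=1).mean())
        if rmsd < best:
            best = float(rmsd)
    return best


@dataclass
class PoseCluster:
    members: list[Pose]

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def representative(self) -> Pose:
        # lowest energy; ties resolved by list order (deterministic)
        energies = [(m.energy if m.energy is not None else np.inf, i)
                    for i, m in enumerate(self.members)]
        _, idx = min(energies)
        return self.members[idx]


def butina_cluster(poses: list[Pose], cutoff: float = BUTINA_CUTOFF) -> list[PoseCluster]:
    """Butina clustering on the symmetry-RMSD matrix.

    Neighbours iff RMSD <= cutoff (inclusive); the pose with the most
    unassigned neighbours seeds each cluster (ties -> lower pose index).
    """
    if not poses:
        raise ContractError("butina_cluster needs at least one pose")
    n = len(poses)
    neigh = np.zeros((n, n), dtype=bool)
    np.fill_diagonal(neigh, True)
    for i in range(n):
        for j in range(i + 1, n):
            if symmetry_rmsd(poses[i], poses[j]) <= cutoff:
                neigh[i, j] = neigh[j, i] = True
    unassigned = np.ones(n, dtype=bool)
    clusters: list[PoseCluster] = []
    while unassigned.any():
        counts = (neigh & unassigned[None, :]).sum(axis=1)
        counts[~unassigned] = -1
        seed = int(np.argmax(counts))          # first max -> lowest index
        member_idx = np.where(neigh[seed] & unassigned)[0]
        clusters.append(PoseCluster([poses[i] for i in member_idx]))
        unassigned[member_idx] = False
    return clusters


def overlap_score(pose: Pose, ensemble: TemplateEnsemble,
                  radius: float = OVERLAP_RADIUS) -> float:
    """Fraction of pose heavy atoms within *radius* of any pooled
    template-ligand heavy atom."""
    pool = ensemble.pooled_heavy_coords()
    if pool.shape[0] == 0:
        warnings.warn("empty template ensemble; overlap set to 0")
        return 0.0
    tree = cKDTree(pool)
    d, _ = tree.query(pose.coords(), k=1)
    return float(np.mean(d <= radius))


FEATURE_NAMES = (
    "anchor_rmsd",
    "overlap",
    "min_contact_dist",
    "mean_contact_dist",
    "n_contacts_4A",
    "strain",
    "n_heavy_atoms",
    "n_rotatable_bonds",
)


def pose_features(pose: Pose, receptor: Receptor,
                  strain: float | None = None) -> np.ndarray:
    """Rigid-motion-invariant feature vector for the confidence model.

    Unset pose fields are imputed to 0 (documented rule).
    """
    xyz = pose.coords()
    rec = receptor.heavy_coords(polymer_only=True)
    if rec.shape[0]:
        d = cKDTree(rec).query(xyz, k=1)[0]
        min_d = float(np.min(d))
        mean_d = float(np.mean(np.minimum(d, 10.0)))
        n_contacts = float(np.sum(d <= CONTACT_SHELL))
    else:
        min_d, mean_d, n_contacts = 10.0, 10.0, 0.0
    mol = pose.molecule.rdmol
    return np.array([
        pose.anchor_rmsd if pose.anchor_rmsd is not None else 0.0,
        pose.overlap if pose.overlap is not None else 0.0,
        min_d,
        mean_d,
        n_contacts,
        strain if strain is not None else 0.0,
        float(mol.GetNumHeavyAtoms()),
        float(rdMolDescriptors.CalcNumRotatableBonds(mol)),
    ])


@dataclass
class ConfidenceModel:
    feature_names: tuple[str, ...] = FEATURE_NAMES
    kind: str = "ridge"                  # ridge | gbrt
    coef: np.ndarray | None = None       # ridge parameters (standardized space)
    intercept: float = 0.0
    mu: np.ndarray | None = None
    sigma: np.ndarray | None = None
    gbrt: object | None = None
    training_meta: dict = field(default_factory=dict)

    @property
    def trained(self) -> bool:
        return self.coef is not None or self.gbrt is not None

    def predict_features(self, X: np.ndarray) -> np.ndarray:
        if not self.trained:
            raise ContractError("confidence model is untrained")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.kind == "gbrt":
            y = self.gbrt.predict(X)
        else:
            Z = (X - self.mu) / self.sigma
            y = Z @ self.coef + self.intercept
        return np.maximum(y, 0.0)        # nonnegativity clamp

    def to_json(self) -> str:
        if self.kind != "ridge" or not self.trained:
            raise ContractError("only trained ridge models serialize to JSON")
        return json.dumps({
            "version": 1,
            "kind": self.kind,
            "feature_names": list(self.feature_names),
            "coef": self.coef.tolist(),
            "intercept": self.intercept,
            "mu": self.mu.tolist(),
            "sigma": self.sigma.tolist(),
            "training_meta": self.training_meta,
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ConfidenceModel":
        d = json.loads(text)
        return cls(
            feature_names=tuple(d["feature_names"]),
            kind=d["kind"],
            coef=np.array(d["coef"], dtype=float),
            intercept=float(d["intercept"]),
            mu=np.array(d["mu"], dtype=float),
            sigma=np.array(d["sigma"], dtype=float),
            training_meta=d.get("training_meta", {}),
        )


def _strains(decoys) -> list[float]:
    """Internal strain = energy minus the per-molecule minimum energy."""
    by_graph: dict[str, float] = {}
    keys, energies = [], []
    for pose, _receptor, _rmsd in decoys:
        key = Chem.MolToSmiles(pose.molecule.rdmol)
        e = pose.energy if pose.energy is not None else 0.0
        keys.append(key)
        energies.append(e)
        by_graph[key] = min(by_graph.get(key, np.inf), e)
    return [e - by_graph[k] for k, e in zip(keys, energies)]


def fit_confidence(decoys: list[tuple[Pose, Receptor, float]], seed: int = 0,
                   kind: str = "ridge", alpha: float = 1.0,
                   holdout_fraction: float = 0.2) -> ConfidenceModel:
    """Fit the RMSD-confidence regressor on a decoy set (MSE objective).

    Requires >= 100 decoys spanning >= 3 Angstrom of RMSD; reports
    held-out MSE and Spearman rank correlation in ``training_meta``.
    """
    if len(decoys) < 100:
        raise ContractError(f"need >= 100 decoys, got {len(decoys)}")
    y = np.array([r for _, _, r in decoys], dtype=float)
    if y.max() - y.min() < 3.0:
        raise ContractError("decoy RMSD range below 3 Angstrom")
    if np.allclose(y, y[0]):
        raise ContractError("degenerate constant-RMSD decoy set")
    strains = _strains(decoys)
    X = np.array([pose_features(p, r, strain=s)
                  for (p, r, _), s in zip(decoys, strains)])
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(y))
    n_hold = max(1, int(round(holdout_fraction * len(y))))
    hold, train = idx[:n_hold], idx[n_hold:]

    model = ConfidenceModel(kind=kind)
    if kind == "gbrt":
        from sklearn.ensemble import GradientBoostingRegressor
        gb = GradientBoostingRegressor(random_state=seed)
        gb.fit(X[train], y[train])
        model.gbrt = gb
    elif kind == "ridge":
        mu = X[train].mean(axis=0)
        sigma = X[train].std(axis=0)
        sigma[sigma < 1e-12] = 1.0
        Z = (X[train] - mu) / sigma
        from sklearn.linear_model import Ridge
        rr = Ridge(alpha=alpha, random_state=seed)
        rr.fit(Z, y[train])
        model.coef = np.asarray(rr.coef_, dtype=float)
        model.intercept = float(rr.intercept_)
        model.mu = mu
        model.sigma = sigma
    else:
        raise ContractError(f"unknown regressor kind {kind!r}")

    pred_hold = model.predict_features(X[hold])
    mse = float(np.mean((pred_hold - y[hold]) ** 2))
    if len(hold) > 2 and np.std(y[hold]) > 0:
        rho = float(spearmanr(pred_hold, y[hold]).statistic)
    else:
        rho = float("nan")
    model.training_meta = {
        "n": len(y), "seed": seed, "loss": "mse",
        "holdout_mse": mse, "holdout_spearman": rho,
    }
    logger.info("confidence model: holdout MSE %.4f, Spearman %.3f", mse, rho)
    return model


def predict_confidence(model: ConfidenceModel, pose: Pose,
                       receptor: Receptor, strain: float | None = None) -> float:
    """Predicted pose RMSD (Angstrom, nonnegative, rigid-motion invariant)."""
    if not model.trained:
        raise ContractError("confidence model is untrained")
    return float(model.predict_features(
        pose_features(pose, receptor, strain=strain))[0])


@dataclass
class RankedPrediction:
    pose: Pose
    rank: int
    composite: float
    cluster_size: int
    overlap: float
    predicted_rmsd: float | None


def _z(values: np.ndarray) -> np.ndarray:
    sd = values.std()
    if sd < 1e-12:
        return np.zeros_like(values)
    return (values - values.mean()) / sd


def rank(clusters: list[PoseCluster], ensemble: TemplateEnsemble,
         model: ConfidenceModel | None, receptor: Receptor,
         top_n: int = 5,
         weights: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> list[RankedPrediction]:
    """Composite prioritization of cluster representatives.

    composite = w1*z(log10 size) + w2*z(overlap) - w3*z(predicted RMSD),
    z-scored across representatives (raw components for a single
    cluster).  Ties break by lower energy, then pose (cluster) index.
    """
    if not clusters:
        raise ContractError("rank needs at least one cluster")
    reps = [c.representative for c in clusters]
    sizes = np.array([c.size for c in clusters], dtype=float)
    overlaps = np.array([overlap_score(r, ensemble) for r in reps])
    for r, o in zip(reps, overlaps):
        r.overlap = float(o)
    if model is not None and model.trained:
        preds = np.array([predict_confidence(model, r, receptor) for r in reps])
        for r, p in zip(reps, preds):
            r.predicted_rmsd = float(p)
    else:
        preds = None

    log_size = np.log10(sizes)
    if len(clusters) == 1:
        composite = log_size + overlaps - (preds if preds is not None else 0.0)
    else:
        composite = weights[0] * _z(log_size) + weights[1] * _z(overlaps)
        if preds is not None:
            composite -= weights[2] * _z(preds)
    order = sorted(
        range(len(clusters)),
        key=lambda i: (
            -composite[i],
            reps[i].energy if reps[i].energy is not None else np.inf,
            i,
        ))
    out = []
    for rank_pos, i in enumerate(order[:top_n], start=1):
        out.append(RankedPrediction(
            pose=reps[i], rank=rank_pos, composite=float(composite[i]),
            cluster_size=int(sizes[i]), overlap=float(overlaps[i]),
            predicted_rmsd=float(preds[i]) if preds is not None else None))
    return out
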