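"""End-to-end orchestration: template search -> alignment -> pharmacophore
-> anchoring -> sampling -> ranking, with a structured run report."""

from __future__ import annotations

import json
import logging
import time
import tomllib
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from . import anchor as anchor_mod
from . import pharmacophore as pharm_mod
from .align import AlignmentError, TemplateEnsemble, build_ensemble
from .anchor import NoAnchorError, NoMatchError
from .ranking import (ConfidenceModel, butina_cluster, overlap_score, rank,
                      symmetry_rmsd)
from .sampling import (Pose, SamplingConfig, clash_filter, embed_anchored,
                       minimize_restrained, sample_torsions_anchored)
from .structures import (ContractError, Receptor, SmallMolecule,
                         parse_small_molecule, read_receptor, write_poses)
from .templates import (TemplateComplex, compute_sequence_identity,
                        extract_ligands, filter_templates, rank_templates)

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig", "RunReport", "NoTemplateError", "NoPoseError",
    "load_config", "harvest_templates", "run_pipeline", "evaluate_success",
]

SUCCESS_CUTOFF = 2.5  # Angstrom, inclusive


class NoTemplateError(RuntimeError):
    """No template passes the identity filter (exit status 10)."""


class NoPoseError(RuntimeError):
    """No pose survives filtering (exit status 11)."""


@dataclass
class PipelineConfig:
    min_identity: float = 0.50
    mcs_timeout_s: float = 10.0
    pharmacophore_radius: float = 1.5
    min_support: int = 2
    site_radius: float = 1.5
    max_matches: int = 32
    sampling: SamplingConfig = field(default_factory=SamplingConfig)
    torsional_steps: int = 0          # 0 disables the torsional stage
    butina_cutoff: float = 0.5
    overlap_radius: float = 1.5
    top_n: int = 5
    max_templates: int = 3            # ranked templates tried before giving up
    rank_weights: tuple[float, float, float] = (1.0, 1.0, 1.0)
    seed: int = 0


def load_config(path: str | Path | None) -> PipelineConfig:
    """Read a TOML config; keys mirror the dataclass fields, sampling
    keys live under a [sampling] table."""
    cfg = PipelineConfig()
    if path is None:
        return cfg
    try:
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
    except (OSError, tomllib.TOMLDecodeError) as exc:
        raise ContractError(f"cannot read config {path}: {exc}") from exc
    sampling_data = data.pop("sampling", {})
    for key, value in data.items():
        if not hasattr(cfg, key):
            raise ContractError(f"unknown config key {key!r}")
        if key == "rank_weights":
            value = tuple(value)
        setattr(cfg, key, value)
    samp = {}
    for key, value in sampling_data.items():
        if not hasattr(cfg.sampling, key):
            raise ContractError(f"unknown sampling config key {key!r}")
        samp[key] = value
    cfg.sampling = replace(cfg.sampling, **samp)
    cfg.sampling = replace(cfg.sampling, seed=cfg.seed)
    return cfg


@dataclass
class RunReport:
    counts: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)
    wall_clock_s: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {"counts": self.counts, "seeds": self.seeds,
             "config": self.config, "wall_clock_s": self.wall_clock_s},
            indent=2, default=str)


def harvest_templates(target: Receptor, template_dir: str | Path,
                      cfg: PipelineConfig) -> list[TemplateComplex]:
    """Read every PDB file in *template_dir* and build one TemplateComplex
    per harvested ligand, with identity to the target's longest chain."""
    target_seq = target.chain_sequences[target.longest_chain()]
    out: list[TemplateComplex] = []
    paths = sorted(Path(template_dir).glob("*.pdb"))
    for path in paths:
        try:
            structure = read_receptor(path.read_text())
        except Exception as exc:
            logger.warning("skipping %s: %s", path.name, exc)
            continue
        if not structure.chain_sequences:
            logger.warning("skipping %s: no polymer chain", path.name)
            continue
        seq = structure.chain_sequences[structure.longest_chain()]
        identity = compute_sequence_identity(target_seq, seq)
        for ligand in extract_ligands(structure):
            out.append(TemplateComplex(
                source_id=f"{path.stem}:{ligand.name}",
                receptor=structure, ligand=ligand, identity=identity))
    return out


def _stage(report: RunReport, name: str, t0: float) -> float:
    now = time.perf_counter()
    report.wall_clock_s[name] = round(now - t0, 4)
    return now


def run_pipeline(target_receptor: Receptor, target_ligand: SmallMolecule,
                 templates: list[TemplateComplex],
                 cfg: PipelineConfig | None = None,
                 confidence_model: ConfidenceModel | None = None,
                 ) -> tuple[list, RunReport, TemplateEnsemble]:
    """Run the full protocol on in-memory inputs.

    Returns (ranked predictions, run report, ensemble).  Raises
    :class:`NoTemplateError` / :class:`NoPoseError` for the two
    structured failure modes.
    """
    cfg = cfg or PipelineConfig()
    report = RunReport(seeds={"seed": cfg.seed},
                       config={"sampling": asdict(cfg.sampling)})
    t0 = time.perf_counter()

    report.counts["templates_found"] = len(templates)
    retained = filter_templates(templates, cfg.min_identity)
    report.counts["templates_identity_filtered"] = len(retained)
    if not retained:
        raise NoTemplateError(
            f"no template at identity >= {cfg.min_identity:.2f}")
    ranked = rank_templates(target_ligand, retained, timeout_s=cfg.mcs_timeout_s)
    report.counts["templates_ranked"] = len(ranked)
    t0 = _stage(report, "template_search", t0)

    ensemble = build_ensemble(target_receptor, ranked)
    t0 = _stage(report, "ensemble_align", t0)

    features = []
    for member in ensemble.members:
        features.extend(pharm_mod.assign_features(member.ligand_in_target_frame))
    sites = pharm_mod.cluster_conserved(
        features, radius=cfg.pharmacophore_radius, min_support=cfg.min_support)
    report.counts["conserved_sites"] = len(sites)
    t0 = _stage(report, "pharmacophore", t0)

    all_poses: list[Pose] = []
    n_patterns = 0
    n_mappings = 0
    n_generated = 0
    n_clash_kept = 0
    for member in ensemble.members[:cfg.max_templates]:
        try:
            try:
                pattern = anchor_mod.build_pattern(
                    member.mcs, sites, member.template,
                    ligand_in_target_frame=member.ligand_in_target_frame,
                    site_radius=cfg.site_radius)
            except NoAnchorError:
                pattern = anchor_mod.full_mcs_pattern(
                    member.mcs, member.template,
                    ligand_in_target_frame=member.ligand_in_target_frame)
            n_patterns += 1
            mappings = anchor_mod.match_pattern(
                pattern, target_ligand, max_matches=cfg.max_matches)
        except (NoAnchorError, NoMatchError) as exc:
            logger.info("template %s unusable: %s", member.template.source_id, exc)
            continue
        n_mappings += len(mappings)
        for mapping in mappings:
            poses = embed_anchored(target_ligand, mapping, cfg.sampling)
            n_generated += len(poses)
            kept = [p for p in poses
                    if clash_filter(p, target_receptor, cfg.sampling.clash_cutoff)]
            n_clash_kept += len(kept)
            minimized = [minimize_restrained(p, target_receptor, cfg.sampling)
                         for p in kept]
            all_poses.extend(minimized)
            if cfg.torsional_steps > 0 and minimized:
                extra = sample_torsions_anchored(
                    target_ligand, mapping, target_receptor,
                    steps=cfg.torsional_steps, seed=cfg.seed, cfg=cfg.sampling,
                    start_pose=minimized[0])
                extra = [p for p in extra
                         if clash_filter(p, target_receptor, cfg.sampling.clash_cutoff)]
                all_poses.extend(extra)
        if all_poses:
            break
    report.counts["patterns_built"] = n_patterns
    report.counts["mappings_matched"] = n_mappings
    report.counts["conformers_generated"] = n_generated
    report.counts["conformers_after_clash_filter"] = n_clash_kept
    report.counts["conformers_minimized"] = len(all_poses)
    t0 = _stage(report, "sampling", t0)

    if not all_poses:
        raise NoPoseError("no pose survived sampling and filtering")

    clusters = butina_cluster(all_poses, cutoff=cfg.butina_cutoff)
    report.counts["clusters"] = len(clusters)
    predictions = rank(clusters, ensemble, confidence_model, target_receptor,
                       top_n=cfg.top_n, weights=cfg.rank_weights)
    report.counts["predictions_emitted"] = len(predictions)
    _stage(report, "ranking", t0)
    return predictions, report, ensemble


def run_pipeline_files(receptor_path: str | Path, ligand_smiles: str,
                       template_dir: str | Path,
                       config_path: str | Path | None = None,
                       confidence_model: ConfidenceModel | None = None):
    """File-based front end used by the CLI: returns (sdf_text, report)."""
    cfg = load_config(config_path)
    target = read_receptor(Path(receptor_path).read_text())
    ligand = parse_small_molecule(ligand_smiles, name="target")
    templates = harvest_templates(target, template_dir, cfg)
    predictions, report, _ = run_pipeline(
        target, ligand, templates, cfg, confidence_model)
    poses = []
    for pred in predictions:
        pose = pred.pose
        pose.molecule.name = f"rank_{pred.rank}"
        poses.append(pose)
    sdf_text = write_poses(poses)
    return sdf_text, report


def evaluate_success(predicted: Pose, reference: Pose,
                     cutoff: float = SUCCESS_CUTOFF) -> tuple[float, bool]:
    """Symmetry-corrected RMSD plus the success flag (rmsd <= cutoff,
    inclusive boundary)."""
    rmsd = symmetry_rmsd(predicted, reference)
    return rmsd, rmsd <= cutoff
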