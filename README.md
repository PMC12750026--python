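# anchordock

Template-based small-molecule pose prediction. Given a target receptor
(PDB), a target ligand (SMILES) and a local directory of holo template
complexes, the pipeline produces ranked ligand poses anchored on
conserved pharmacophoric substructures:

1. **Template search** — harvest ligands from every template PDB, filter
   templates at ≥ 50% sequence identity to the target (global alignment,
   BLOSUM62, gap open 11 / extend 1), rank by the fraction of target
   heavy atoms covered by the maximum common substructure (MCS).
2. **Ensemble alignment** — superpose each template receptor onto the
   target (sequence-guided iterative Kabsch, 2.0 Å outlier rejection,
   5 cycles) and pool all template ligands in the target frame.
3. **Pharmacophore** — type ligand atoms (donor / acceptor / aromatic /
   hydrophobic / cation / anion via a documented SMARTS dictionary) and
   cluster features across the aligned ensemble into conserved sites.
4. **Anchoring** — MCS atoms overlapping conserved sites are expanded to
   connected template-ligand fragments and rendered as a composite
   (possibly disconnected, `.`-joined) generalized SMARTS pattern; each
   match on the target ligand fixes anchor-atom coordinates.
5. **Sampling** — constrained ETKDG embedding (up to 1000 conformers per
   atomic mapping, anchor atoms fixed to template coordinates), steric
   clash filter (pose discarded when any ligand–receptor heavy-atom
   distance < 1.5 Å), 500 steps of restrained minimization (internal
   simplified force field; backbone frozen, side chains mobile, harmonic
   anchor restraints of 10 kcal·mol⁻¹·Å⁻²; a full MM engine can be
   injected through the same interface). An annealed anchored torsional
   Metropolis sampler is available as an optional extra stage.
6. **Ranking** — Butina clustering on symmetry-corrected heavy-atom RMSD
   (0.5 Å cutoff), lowest-energy representative per cluster,
   template-ensemble overlap score, RMSD-confidence prediction from an
   invariant-feature regressor, and composite prioritization
   `z(log10 size) + z(overlap) − z(predicted RMSD)`.

Success is evaluated by symmetry-corrected RMSD with a 2.5 Å cutoff
(inclusive).

## CLI

```bash
# generate the seeded synthetic toy system (pocket + holo templates)
anchordock fixtures --seed 1 --out-dir fixtures/

# stage-by-stage
anchordock templates --receptor fixtures/target.pdb --ligand "Cc1ccc(CCO)cc1" --template-dir fixtures/
anchordock anchor    --receptor fixtures/target.pdb --ligand "Cc1ccc(CCO)cc1" --template-dir fixtures/ --out anchor.json
anchordock sample    --receptor fixtures/target.pdb --ligand "Cc1ccc(CCO)cc1" --template-dir fixtures/ --out poses.sdf

# end to end (SDF + JSON run report)
anchordock run --receptor fixtures/target.pdb --ligand "Cc1ccc(CCO)cc1" \
    --template-dir fixtures/ --out predictions.sdf --report run_report.json

# score predictions against a reference pose
anchordock eval --predicted predictions.sdf --reference fixtures/reference.sdf
```

Exit statuses: `0` success, `10` no template passes the identity filter,
`11` no pose survives filtering, `2` configuration error.

Configuration is TOML; every numeric protocol default is a key
(`min_identity`, `butina_cutoff`, `top_n`, …; sampling keys under
`[sampling]`: `n_max`, `clash_cutoff`, `minimize_steps`,
`anchor_tolerance`, `restraint_k`, `seed`, …). CLI flags override the
file. A fixed seed makes the whole run byte-reproducible.

## Layout

```
src/anchordock/
  structures.py     PDB/SDF/SMILES I/O, Receptor and SmallMolecule types
  templates.py      ligand harvesting, identity filter, MCS, ranking
  align.py          Kabsch superposition, template ensemble
  pharmacophore.py  feature SMARTS dictionary, conserved-site clustering
  anchor.py         composite SMARTS construction and matching
  engine.py         simplified force field + steepest-descent minimizer
  sampling.py       constrained embedding, clash filter, minimization,
                    annealed torsional sampler
  ranking.py        symmetry RMSD, Butina, overlap, confidence model, rank
  fixtures.py       synthetic toy systems, sequence mutator, decoy sets
  pipeline.py       orchestration, run report, success evaluation
  cli.py            click command group
tests/              pytest suite (unit, property, acceptance)
scripts/acceptance.py
```
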