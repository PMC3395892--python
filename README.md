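# pentamut

Predict whether a single amino acid substitution changes local protein
backbone structure.

The pipeline compares pairs of pentamers (five consecutive residues) that
are identical except at the central position and come from sufficiently
similar proteins. Each pair is superposed optimally on its five C-alpha
atoms; the resulting RMSD labels the pair *neutral* (< 0.2 Å), *change*
(> 0.4 Å) or *excluded* (in between). Sequence-derived features — global
chain descriptors, local per-residue tracks in windows of 1–21 residues,
and wild-type/mutant difference channels — feed an L2-regularized
logistic regression. Features are chosen by greedy forward selection on
mean cross-validated AUC with homology-aware folds (similar proteins never
straddle a train/test boundary), and predictions are scored with
class-specific accuracy/coverage, ROC/AUC and enrichment analyses.

External predictors (profile searches, secondary-structure/accessibility/
disorder/flexibility predictors, domain scans, conservation scores) are
*not* executed here; their per-residue outputs are consumed as plain TSV
tracks or as PSI-BLAST ASCII PSSM files, and a synthetic-fixture module
provides range-correct stand-ins for every slot.

## Layout

| Module                      | Role |
| --------------------------- | ---- |
| `pentamut.structure_io`     | PDB parsing (altloc/non-standard rules), chain-break detection, FASTA/TSV output |
| `pentamut.fragments`        | pentamer extraction, global identity, pairing, maximal-fragment filter, role designation |
| `pentamut.superposition`    | Kabsch SVD superposition with reflection guard, RMSD, three-way labeling |
| `pentamut.features`         | propensity scales, track/PSSM parsing, window/difference encoding, vector assembly |
| `pentamut.selection`        | homology-aware folds and holdout split, forward selection, logistic model |
| `pentamut.evaluation`       | confusion counts, Q2, accuracy/coverage, ROC/AUC, enrichment, ΔΔG labels, box stats |
| `pentamut.synthetic`        | toy backbones, mutant pair fixtures, synthetic tracks, planted-AUC datasets |
| `pentamut.cli`              | `pentamut` command-line entry point |

## CLI

Every step is exposed as a subcommand; all inputs and outputs are plain
text (PDB, TSV, JSON). A full desk-scale run:

```sh
pentamut simulate pairs  --n 20 --length 25 --perturb 0.4 --seed 1 --out fixtures
pentamut simulate tracks --pdb-dir fixtures/wt  --seed 2 --out tracks
pentamut simulate tracks --pdb-dir fixtures/mut --seed 2 --out tracks
pentamut build-pairs --set-a fixtures/wt --set-b fixtures/mut --seed 3 --out pairs.tsv
pentamut label-pairs --pairs pairs.tsv --pdb-dir fixtures/wt --pdb-dir fixtures/mut
pentamut encode --pairs pairs.tsv --pdb-dir fixtures/wt --pdb-dir fixtures/mut \
    --tracks-dir tracks --out matrix.tsv
pentamut train    --matrix matrix.tsv --labels labels.tsv --out model.json
pentamut predict  --model model.json --matrix matrix.tsv --out preds.tsv
pentamut evaluate --predictions preds.tsv --labels labels.tsv --out report.json
pentamut enrich   --predictions preds.tsv --effects ddg.tsv
```

`pentamut simulate dataset` produces planted-signal Gaussian matrices with
a known analytic AUC, and `pentamut select-features` runs the forward
selection over a matrix's layout groups.

## Conventions worth knowing

- Thresholds are strict: RMSD exactly at 0.2/0.4 Å is excluded, a
  probability of exactly 0.5 predicts neutral, ΔΔG of exactly ±1 kcal/mol
  is neutral.
- Difference features use mutant − wild type; ties get sign bit 1.
- PSSM scores are scaled from [−16, 16] to [0, 1]; information content is
  capped at 2 bits. These constants are documented configuration, not
  claims about any upstream tool.
- Pairs embedded in an identical-except-center region extending more than
  4 residues (total, left+right; configurable) are discarded.
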