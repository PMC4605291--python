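# idrbind

Sequence-based, per-residue prediction of RNA-, DNA- and protein-binding
mediated by intrinsic disorder.

An input protein sequence is represented by per-residue channels —
normalized amino-acid scale profiles, sliding-window amino-acid composition,
windowed Shannon-entropy sequence complexity, and pluggable putative
disorder / secondary-structure scores. Function-specific sliding windows
(defaults 55/21/33 for RNA/DNA/protein binding, or the 20th centile of the
training region lengths) turn the channels into near-vs-remote contrast and
window-mean features, which are filtered by a two-stage relevance/redundancy
selection and scored by one ridge-penalized logistic regression per binding
function. Binary annotations transferred by local alignment against the
training library (E-value < 0.1, best hit) are merged into the regression
propensity as `(1+p)/2`. Binding regions are maximal runs of ≥ 4 residues
with propensity ≥ 0.5.

The package also ships the full assessment stack (per-residue ROC/AUC,
TP-rate at a fixed FP-rate, subset-resampling significance with an
Anderson–Darling-gated t / Wilcoxon test, FP-rates on matched control
regions), proteome-level validation analyses (reference-set overlap vs
random baseline, localization enrichment with a 2% low-count filter,
promiscuity–region-count correlation, linear-motif overlap), and a seeded
synthetic-corpus generator with planted, tunable signal so every stage is
testable without external downloads.

## CLI

A single executable with subcommands:

```bash
# seeded synthetic corpus (FASTA + region TSV + metadata)
idrbind simulate --n-proteins 200 --effect-size 1.0 --seed 1 --out corpus/

# train the three per-function models (window sizes derived from the corpus)
idrbind train --fasta corpus/corpus.fasta --annotations corpus/regions.tsv \
    --out models/

# predict: per-residue propensity TSV + called-region TSV
idrbind predict --fasta query.fasta --models-dir models/ --out pred/
idrbind predict --fasta query.fasta --models-dir models/ --no-transfer --out pred_ablate/

# per-residue ROC/AUC evaluation against annotations
idrbind evaluate --predictions pred/predictions.tsv --fasta query.fasta \
    --annotations truth.tsv --out eval/

# proteome-level overlap (and optional promiscuity) analyses
idrbind proteome --regions pred/regions.tsv --reference known_binders.txt \
    --proteome proteome_ids.txt --function rna --out prot/
```

Thresholds default to `--cutoff 0.5`, `--e-cutoff 0.1`,
`--min-region-len 4`; window sizes can be forced with
`--ws-rna/--ws-dna/--ws-protein`. Every command echoes its configuration to
`config.json` and logs counts to `run.log` in the output directory.

## File formats (all plain text)

- sequences: FASTA
- annotations / called regions: 4-column TSV `protein_id  function  start  end`
  (1-based inclusive; functions `disorder|rna|dna|protein`), regions output
  adds a `mean_propensity` column
- per-residue predictions: TSV `protein_id position residue p_rna p_dna
  p_prot b_rna b_dna b_prot`
- scales: TSV `scale_id` + 20 values in the order `ACDEFGHIKLMNPQRSTVWY`
- external disorder/secondary-structure scores: TSV
  `protein_id position channel score`
- alignments (external engine): standard 12-column tabular format
- models: versioned key/value text with one row per feature
  (id, coefficient, standardization mean/std)
- proteome tables: id lists (one per line), degree TSV, localization TSV

## Layout

```
src/idrbind/
  annotations.py   sequences, region records, per-residue tracks
  scales.py        bundled amino-acid scale library + normalization
  profiles.py      per-residue channels (scales, composition, complexity,
                   disorder/secondary-structure providers)
  features.py      window geometry, contrast features, feature selection
  model.py         ridge logistic regression, model files
  transfer.py      alignment search, annotation transfer, (1+p)/2 merge
  regions.py       binarization, region and binder calls
  evaluate.py      ROC/AUC, TP@FP, subset significance, control FP-rates
  proteome.py      overlap / localization / promiscuity / motif analyses
  simulate.py      seeded synthetic corpora with planted signal
  workflow.py      train/predict pipelines
  cli.py           command-line interface
```
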