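# foldrate

Machine-learning prediction of how single amino acid substitutions
change the folding rate of two-state proteins. Two predictors are
provided:

* a **three-class classifier** (folding rate *decrease* / *no effect* /
  *increase*, thresholded at |Δln kf| = 0.15) built as a voting ensemble
  of ten gradient-boosted tree sub-models, each trained on a
  class-balanced under-sample (default 80 records per class);
* a **regression predictor** of Δln kf = ln kf(variant) − ln kf(wild type).

Supporting machinery includes the full 1161-dimensional feature
extraction (six families: amino acid index differences and pair-matrix
lookups, conservation/coevolution, one-hot variation type, sequence
neighborhood composition, relative position, and secondary structure +
relative solvent accessibility), iterative weighted-importance feature
selection over repeated grouped cross-validation partitions, a
grouped 10×5-fold CV driver, the complete metric suite (SPEC/SENS/F1,
macro-F1, ACC, GC2; PCC/MAE/MSE/R2), and a synthetic-data generator so
that every stage is testable offline.

## Input formats

* **Variants** — TSV with header `protein_id`, then either a compact
  `substitution` column (`A25F`) or `wt_aa`/`position`/`var_aa`, plus
  `kf_wt`+`kf_var` (s⁻¹) and/or `delta_lnkf`. `#` lines are comments.
* **Sequences** — FASTA, ids matching `protein_id`.
* **Structure annotation** — TSV `protein_id, position, ss_class, asa`
  with 7-state secondary structure (H/G/I/E/B/T/C) and ASA in Å²; RSA is
  derived internally via a bundled maxASA table. Alternatively a PDB
  file can be fed through the reference Shrake–Rupley ASA computation
  (`foldrate.features.structure.compute_asa`).
* **Conservation annotation** — TSV `protein_id, position, c_score,
  coev_max, coev_partners` (an alignment-entropy fallback exists).

Bundled feature data (`src/foldrate/features/data/`): amino acid index
tables (553 single + 135 pair indices; see the file headers for
provenance — pair-matrix values are deterministic placeholders that can
be replaced by real AAindex flat files), the maxASA table, the six-way
residue grouping, and the two published selected-feature lists
(`classifier31`, `regressor21`).

## CLI

```sh
foldrate simulate --n-variants 300 --seed 1 --out fixtures/
foldrate summarize --variants fixtures/variants.tsv --fasta fixtures/sequences.fasta
foldrate train    --task classify --subset classifier31 --seed 1 \
    --variants fixtures/variants.tsv --fasta fixtures/sequences.fasta \
    --structure fixtures/structure.tsv --conservation fixtures/conservation.tsv \
    --out run/
foldrate predict  --model run/model --out run/predictions.tsv \
    --variants fixtures/variants.tsv --fasta fixtures/sequences.fasta \
    --structure fixtures/structure.tsv --conservation fixtures/conservation.tsv
foldrate evaluate --task regress --mode cv --subset regressor21 ... --out eval/
foldrate select-features --task classify --max-size 31 ... --out selection/
```

Every command is deterministic for a fixed seed; models are saved as
hash-validated bundle directories.

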