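# lfqpanel

Label-free LC-MS proteomics analysis pipeline for four-group case/control
biomarker discovery:

* **Top-3 quantification** — peptide-level intensities to a normalized,
  replicate-averaged protein × sample abundance matrix (identification
  filter at ≥2 unique peptides, mean of the three most intense peptides,
  summed-intensity normalization, technical-replicate averaging, per-group
  CVs).
* **Differential expression** — DVD (case) vs NC / T2DM / VD contrasts with
  a zero-pattern rule: proteins majority-zero in one group and
  majority-nonzero in the other are group-specific with p designated 0;
  majority-nonzero proteins get a pooled-variance t-test on log2 of the
  nonzero values, thresholds p < 0.05 and FC < 0.83 or > 1.20; three-way
  common-DEP overlap and volcano coordinates.
* **Diagnostic markers** — DVD vs pooled-others ROC analysis: tie-corrected
  Mann–Whitney AUC, DeLong confidence intervals, Wilcoxon rank-sum p,
  optimal cutpoint by the squared Euclidean index (1−Se)² + (1−Sp)²,
  sensitivity at 95% specificity, and two-marker composites via logistic
  regression on standardized abundances.
* **Enrichment** — one-sided Fisher over-representation analysis against an
  explicit background, with Bonferroni / Holm / BH / BY corrections.
* **Synthetic studies** — a seeded simulator planting differential proteins,
  group-specific proteins, and markers with target AUC, for calibration and
  recovery testing.

## CLI

All stages are subcommands of `lfqpanel` (exit codes: 0 ok, 2 validation
error, 3 I/O error):

```sh
lfqpanel simulate --seed 1 --n-proteins 1000 --out-dir work/
lfqpanel quantify --peptides work/peptides.tsv --metadata work/metadata.tsv \
    --out work/abundance.tsv --min-peptides 2 --top-n 3 --normalize summed_intensity
lfqpanel depcall --matrix work/abundance.tsv --metadata work/metadata.tsv --out-dir work/
lfqpanel markers --matrix work/abundance.tsv --metadata work/metadata.tsv --out work/panel.tsv
lfqpanel enrich --study study.txt --population background.txt \
    --annotations terms.tsv --method bh --out enrichment.tsv
lfqpanel pipeline --seed 1 --out-dir work/   # all stages on a synthetic study
```

All files are plain TSV: a long-format peptide table
(`protein peptide sample replicate intensity`), a metadata table
(`sample group replicate` with groups NC/T2DM/VD/DVD), and matrices with
protein accessions in the first column. Blank matrix cells read as 0
("not detected").

## Library use

```python
from lfqpanel import (SimulationConfig, simulate_study, quantify_study,
                      call_deps, common_deps, DEFAULT_CONTRASTS,
                      candidate_filter, evaluate_panel)

table, metadata, truth = simulate_study(SimulationConfig(seed=1))
matrix = quantify_study(table, metadata)
results = {c.name: call_deps(matrix, metadata, c) for c in DEFAULT_CONTRASTS}
common = common_deps(results)
up, down = candidate_filter(common.common, results, matrix, metadata)
panel = evaluate_panel(up, matrix, metadata)
```
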