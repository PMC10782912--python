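# cfcnv

Copy-number screening from low-pass (~0.2×) cell-free DNA sequencing, for
binary case/control classification. The toolkit builds a samples × windows
coverage matrix from per-sample depth tracks, corrects GC/mappability bias,
prunes uninformative windows, imputes dropout entries with a regularized
low-rank factorization, trains a 1D CNN with a position-wise self-attention
layer (pure numpy, no deep-learning framework required), and maps the learned
attention back to genomic windows to discover discriminative regions, which
can then be annotated to genes and tested for gene-set over-representation.

A synthetic-cohort simulator (`cfcnv.simulate`) generates low-coverage window
counts with GC/mappability bias, Poisson or negative-binomial noise, dropout,
and group-specific copy-number segments with known truth, so the entire
pipeline is testable without any external data.

## Modules

| Module             | Purpose |
|--------------------|---------|
| `cfcnv.windows`    | Non-overlapping genomic windows from chrom.sizes, exclusion-region masking, per-window GC/mappability annotation |
| `cfcnv.covmatrix`  | Per-window coverage counting, sample QC (mean depth ≥ 0.15×, ≥ 6M reads), two-stage GC/mappability bias correction, row normalization, window pruning |
| `cfcnv.impute`     | Dropout flagging and low-rank matrix-completion imputation |
| `cfcnv.nn` / `cfcnv.model` | The CNN+attention classifier: 75/5/20 splitting, training (Adam, BCE), prediction, attention attribution, grid search |
| `cfcnv.evaluate`   | Confusion matrix, accuracy/precision/recall/F1, ROC/AUC, prediction–label correlation, bootstrap AUC CI, stratified k-fold CV |
| `cfcnv.regions`    | Attention-weight ranking (top-k windows), gene annotation, hypergeometric ORA with Benjamini–Hochberg correction |
| `cfcnv.simulate`   | Synthetic cohorts + truth-recovery scoring |
| `cfcnv.cli` / `cfcnv.pipeline` | Stage subcommands and a single-config pipeline runner with a reproducible run manifest |

## CLI

Every pipeline stage is a subcommand; `run` chains them from one YAML config:

```sh
# simulate a toy cohort (windows, counts, labels, truth, depth bedGraphs)
cfcnv --seed 1 simulate --config sim.yaml --depth-files -o cohort/

# stage by stage
cfcnv make-windows --chrom-sizes hg.chrom.sizes --size 10000 \
    --exclude segdup.bed --gc gc.bedgraph --map map.bedgraph -o windows.tsv
cfcnv count --windows windows.tsv --depth sample1.bedgraph -o s1.counts.tsv
cfcnv correct --windows windows.tsv --counts s1.counts.tsv -o s1.corrected.tsv
cfcnv matrix --counts counts.tsv --labels labels.tsv -o matrix.tsv
cfcnv --seed 1 impute --matrix matrix.tsv --rank 10 -o imputed.tsv
cfcnv --seed 1 train --matrix imputed.tsv --config model.yaml -o model/
cfcnv predict --model-dir model/ --matrix imputed.tsv -o pred.tsv
cfcnv --seed 1 evaluate --pred pred.tsv --labels labels.tsv -o report.json
cfcnv attention --model-dir model/ --matrix imputed.tsv -o weights.tsv
cfcnv rank --weights weights.tsv --windows windows.tsv --top 5000 -o top.bed
cfcnv annotate --regions top.bed --genes genes.bed -o genes.txt
cfcnv enrich --genes genes.txt --gmt sets.gmt --universe universe.txt -o ora.tsv

# or everything at once, with a run manifest
cfcnv run --config pipeline.yaml
```

The pipeline config carries one master `seed` from which all stage seeds are
derived, so a rerun with the same config reproduces every deterministic stage
output byte for byte (checked via the manifest's SHA-256 digests).

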