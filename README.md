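# immunopair

Paired-tissue immune profiling toolkit: T-cell receptor (TCR) repertoire
comparison statistics, cross-dataset consensus differential expression via
robust rank aggregation, and gene-signature (inflamed T-cell profile)
scoring — with a synthetic-data generator that carries known ground truth so
the whole pipeline is testable offline.

## What it does

- **`immunopair.repertoire`** — data model and I/O for clonotype tables
  (AIRR Rearrangement TSV and a MiXCR-export dialect). Distinguishes
  *clonotypes* (unique CDR3 amino-acid sequence) from *clones* (unique
  CDR3 + V/D/J combination); frequencies are read-count fractions.
- **`immunopair.repstats`** — clonal-expansion summaries (frequency-bin
  mass above thresholds, top-N proportion), cross-sample clonotype sharing
  (Jaccard, per-sample fractions, Spearman correlation of shared-clonotype
  frequencies), V–J gene-segment usage matrices with filtered pairwise
  correlations, and generic two-group tests (Welch/Student t,
  Mann–Whitney, paired Wilcoxon).
- **`immunopair.metadeg`** — per-dataset preprocessing (log2, quantile
  normalization), Welch-t ranking with Benjamini–Hochberg adjustment,
  robust rank aggregation (beta order-statistic scores) over directional
  ranked lists, and conjunctive DEG calling (aggregated score + per-dataset
  significance/fold-change support) with direction-consistency accounting.
- **`immunopair.signature`** — per-sample signature scores as (weighted)
  means of z-scored gene expression, score–gene correlation, and group
  comparison.
- **`immunopair.simulate`** — paired-tissue repertoires (power-law clone
  sizes, planted cross-tissue sharing, tissue-specific V–J profiles, finite
  sequencing depth) and multi-platform expression matrices (planted DEGs,
  platform shifts, a latent infiltration factor driving signature genes).
  Deterministic given a seed; emits plain-text artifacts plus truth JSON.

## CLI

```sh
# end-to-end synthetic demonstration
immunopair demo --out demo_run --seed 3

# or step by step
immunopair simulate --out data --seed 7 \
    --sharing 'EAT|HEART=0.3,SAT|HEART=0.05' --alpha 'EAT=1.8,SAT=3.0,HEART=2.0'
immunopair repstats --samples data/samples.csv --repdir data/repertoires --out stats
immunopair metadeg --expr data/expression/DS1.csv --expr data/expression/DS2.csv --out deg
immunopair gep --expr data/expression/DS1.csv --signature data/signature.tsv --out gep
```

`immunopair` is also runnable as `python -m immunopair.cli`. Every
subcommand accepts `--config config.yaml`; flags override config entries.
Each run writes `resolved_config.yaml` and `manifest.json` beside its
outputs. Exit codes: 0 success, 1 runtime/data error, 2 parameter error.

Defaults: expansion thresholds 0.001/0.005/0.01 (strictly greater-than),
top-N 10, V–J usage filter 0.01 on the reference-tissue mean, DEG cuts
score 0.05 / adjusted-p 0.05 / |log2FC| 0.5.

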