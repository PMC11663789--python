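# metahet

Single-cell metabolic heterogeneity analysis: from raw multi-sample count
matrices through malignant-cell identification, rank-based metabolic gene-set
scoring, per-sample NMF program extraction and meta-program (MMP) clustering,
abundance and association statistics, to cell-type-specific pseudo-bulk
subtyping.  A synthetic cohort generator plants known cell types, CNV
segments and subpopulation-restricted metabolic gene modules so every stage
has a recoverable ground truth.

## Modules

| Module | Purpose |
| --- | --- |
| `metahet.io_core` | `CellExpression` data model; MTX/TSV/GMT readers and deterministic table writers |
| `metahet.synthetic` | Negative-binomial cohort simulator with planted markers, programs, CNVs and truth tables |
| `metahet.preprocess` | QC filtering (200 genes / 500 UMI / mito cap / dataset downsampling), log-normalization, top-500 metabolic selection, z-score + clip scaling |
| `metahet.malignant` | CNV-lite smoother, quadratic CNV score, iterative score-based 2-means malignancy classifier, CD4/CD8 assignment |
| `metahet.scoring` | AUC recovery-curve gene-set scores, pseudo-bulk rank scores, rank-sum differential tests, metabolic similarity, lineage AUC |
| `metahet.mmp` | Per-sample NMF (K = 4..9), three-criterion robust filter, greedy founder-extension MMP clustering, enrichment annotation, abundance statistic |
| `metahet.association` | Per-tumour correlation screens, co-occurrence network, PVE linear models, fold-change correlation |
| `metahet.subtyping` | Pseudo-bulk construction, resampling consensus clustering (PAC), subtype signatures |

## CLI

Subcommands operate on a 10x-style MTX directory (`matrix.mtx`,
`features.tsv`, `barcodes.tsv`, `meta.tsv`, optional `gene_positions.tsv`):

```sh
metahet simulate --preset malignancy --seed 2 --out sim/
metahet preprocess --in sim/ --out prep/
metahet malignancy --in prep/ --out malig/
metahet score --in prep/ --gmt pathways.gmt --out scores.tsv
metahet differential --in prep/ --group-by cell_type --out de.tsv
metahet mmp --in prep/ --out mmp/
metahet subtype --in prep/ --out subtype/ --k-range 2,3,4
```

`simulate` presets: `basic` (tumour+normal, six lineages), `malignancy`
(planted CNV gains/losses plus a malignant expression module), `mmp`
(30 malignant-epithelium tumours with the 15-module planted catalogue).
Further subcommands: `similarity`, `lineage-auc`, `correlate`, `cooccur`,
`pve`.

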