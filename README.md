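# hifmeta

Derive a consensus HIF (hypoxia-inducible factor) target-gene signature from
replicate ChIP-seq peak lists plus differential-expression tables, score HIF
pathway activation in bulk and single-cell expression matrices with a
quantile-normalized metagene, and run downstream association screens.
Every stage is exercisable on synthetic datasets with planted ground truth,
so the whole chain is testable without any external downloads.

## What's inside

| module | purpose |
| --- | --- |
| `hifmeta.types` | domain types (intervals, binding sites, DE records, expression matrices, signatures, config) |
| `hifmeta.io` | BED / TSV / MatrixMarket / YAML readers and writers |
| `hifmeta.signatures` | the packaged `conserved48` signature fixture |
| `hifmeta.synthetic` | panel / cohort / single-cell generators with planted truth |
| `hifmeta.peaks` | replicate-consensus peaks, background-percentile filter, isoform classification |
| `hifmeta.targets` | k-nearest-gene assignment by TSS distance, bound+upregulated gene calls |
| `hifmeta.derivation` | set-overlap profiles vs independence expectations, consensus derivation, rank-sum test |
| `hifmeta.metagene` | quantile-rank bulk scoring, single-cell control-bin scoring, dropout diagnostics |
| `hifmeta.association` | per-gene correlation screen, cross-dataset sharing counts, pre-ranked GSEA, covariate-adjusted regression, group comparisons |
| `hifmeta.pipeline` | end-to-end chain from peak lists to a consensus signature |
| `hifmeta.cli` | the `hifmeta` command-line interface |

## CLI

```bash
# generate a synthetic 6-line panel with planted consensus targets
hifmeta simulate panel --seed 1 --outdir panel/

# replicate consensus + background filter + isoform classification
hifmeta peaks consensus \
    --h1 panel/peaks_LINE1_h1_rep1.bed panel/peaks_LINE1_h1_rep2.bed \
    --h2 panel/peaks_LINE1_h2_rep1.bed panel/peaks_LINE1_h2_rep2.bed \
    --arnt panel/peaks_LINE1_arnt_rep1.bed panel/peaks_LINE1_arnt_rep2.bed \
    --background panel/background.tsv --percentile 99.99 -o sites_LINE1.bed

# assign sites to genes and call bound + upregulated genes
hifmeta targets assign --sites sites_LINE1.bed \
    --annotation panel/annotation.tsv --de panel/de_LINE1.tsv -k 3 \
    -o targets_LINE1.tsv

# consensus over lines (repeat the two steps above per line first)
hifmeta signature derive --targets targets_LINE1.tsv ... --min-lines 6 \
    -o signature.tsv

# metagene scoring and downstream screens
hifmeta simulate cohort --seed 1 --outdir cohort/
hifmeta score bulk --matrix cohort/matrix.tsv --signature conserved48 -o scores.tsv
hifmeta screen correlate --matrix cohort/matrix.tsv --scores scores.tsv \
    --exclude-signature conserved48 -o corr.tsv
hifmeta compare groups --scores scores.tsv --meta cohort/metadata.tsv \
    --contrast mutated wildtype -o cmp.tsv

# single cells
hifmeta simulate cells --seed 1 --outdir cells/
hifmeta score cells --mtx cells/counts.mtx --genes cells/genes.tsv \
    --barcodes cells/barcodes.tsv --method control_bin --seed 7 -o cell_scores.tsv
```

Global flags `--config <yaml>`, `--seed <int>` and `--log-level` are accepted
before any subcommand.

## Notes

* All coordinates are 0-based, half-open (BED semantics); chromosome names
  are compared as exact strings.
* Bulk metagene scores are cohort-relative (rank-based); do not compare raw
  scores across separately scored cohorts.
* The per-gene membership flags of the 14 published hypoxia signatures in
  the fixture are placeholders pending verification against the formatted
  source table (see `SignatureSet.note`); the gene list itself is exact.
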