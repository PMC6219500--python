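# methphen

Cell-population-resolved DNA methylation analysis: from per-CpG bisulfite
methylation calls through fixed 100-bp binning, covariate-adjusted
differential methylation calling, genomic-context enrichment,
multi-comparison DMR set algebra, and an array-based validation arm
(hierarchical-clustering evaluation and a penalized-logistic CpG signature).
A synthetic-data module generates RRBS-style call files, annotation tracks
and array beta matrices with known ground truth so every stage is testable
without external downloads.

## Pipeline overview

1. **io / binning** — read per-CpG call tables (simple or methratio
   dialects), filter low (`< 3` reads) and high (`> 99.95th` percentile)
   coverage, merge symmetric CpG strand calls, sum counts into
   non-overlapping 100-bp bins, and keep only bins covered in **all**
   samples (the analysis universe).
2. **DMR calling** — per-bin binomial logistic regression of methylated /
   unmethylated counts on the group indicator with the donor of origin as a
   categorical covariate; 1-df likelihood-ratio p-values; sliding-linear-model
   (SLIM) q-values; DMRs are bins with `q < 0.05` and absolute methylation
   difference `> 10%`.
3. **genomic context** — island / shore (2 kb) / shelf (2 kb) classes,
   signed distance to the nearest TSS with a ±5 kb proximal split,
   directional hypergeometric enrichment against the universe (p floored at
   1e-300, E/D labels), conservation profiles and a 1000-iteration
   resampling test for distal-bin conservation.
4. **comparisons** — all six pairwise comparisons of the NB / NL / CB / CL
   populations over one shared universe, Fisher's exact overlap tests, and
   three derived classes: phenotype-shared (NL-NB ∩ CL-CB), CL-specific
   (CL-CB ∩ CL-NL, flagging any NL-NB overlap), cancer-shared
   (CL-NL ∩ CB-NB).
5. **array validation** — probe-to-region mapping, complete-linkage
   clustering of unscaled beta values with tree cutting and TPR / TNR /
   chi-square scoring, and a LASSO logistic signature (70/30 stratified
   split, 200 log-spaced lambdas on [e^-7, e^-2], 10-fold CV, evaluation by
   ROC/AUC and at a 0.8 probability cutoff).

## Command line

```bash
# full config-driven run (simulation + all analysis stages)
methphen run-all --config config.yaml --seed 1 --out runs/demo

# individual stages
methphen simulate  --config config.yaml --out runs/sim
methphen bin       --calls runs/sim/simulated/calls \
                   --sample-sheet runs/sim/simulated/sample_sheet.tsv \
                   --bin-size 100 --min-cov 3 --high-pct 99.95 --out matrix.tsv
methphen dmr       --matrix matrix.tsv --sample-sheet sheet.tsv \
                   --group-a luminal:normal --group-b basal:normal \
                   --covariate donor --out nl_nb.bed
methphen compare   --matrix matrix.tsv --sample-sheet sheet.tsv --out comp/
methphen annotate  --dmr-bed nl_nb.bed --universe-bed universe.bed \
                   --annotation-dir runs/sim/simulated/annotation --out ann/
methphen validate  --beta beta.tsv --sample-sheet array_sheet.tsv
methphen signature --beta beta.tsv --sample-sheet array_sheet.tsv \
                   --train-frac 0.7 --folds 10 --cutoff 0.8 --seed 1 --out sig/
```

Exit codes: 0 success, 2 configuration error, 1 runtime error.  A config
file is a flat YAML mapping; every omitted key takes its standard default
(see `methphen/config.py`).  Runs are deterministic for a fixed seed.

## File formats

* call files: TSV `chrom  pos(1-based)  strand  meth_reads  total_reads`
  (gzip supported); bsmap methratio output also readable.
* sample sheet: TSV `sample_id  donor  phenotype  disease`.
* annotation: BED interval tracks (0-based half-open), TSS point TSV,
  conservation bedGraph.
* bin matrix: TSV with `chrom start end n_cpgs` plus `<sample>.meth` /
  `<sample>.total` column pairs.
* DMRs: BED6+ with score = -log10(q) capped at 300 and meth_diff / p / q /
  direction columns.
* array data: probes × samples beta TSV, manifest TSV
  (`probe_id chrom pos`), sample sheet with normal/cancer labels; trained
  signatures serialize to JSON.

Internally all coordinates are 0-based half-open; 1-based inputs (call
files, probe manifests) are converted at the boundary.
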