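# stsdel

Deletion detection over sequence-tagged sites (STSs) from targeted-capture
read depth. Given a samples × STSs mean-depth matrix and an STS catalog, the
pipeline

1. **filters and normalizes** the matrix (1.5×-IQR outlier removal on both
   axes, a 15× median-depth cutoff per STS, per-sample mean normalization,
   and a 0.7 standard-deviation cap per sample),
2. computes **three predictors** per (sample, STS) pair — the log
   standard-normal density of the standardized depth, depth/RMD (ratio to
   the STS's cross-sample median) and depth/SMD (ratio to the sample's
   cross-STS median),
3. calls deletion states with an **RBF-kernel SVM** (bandwidth
   parameterization `k(x,y) = exp(-|x-y|²/2σ²)`; shipped defaults `C = 2⁹`,
   `σ = 2³`; repeated stratified 4-fold CV grid search over `2⁻⁵…2¹⁵`
   available),
4. **merges** per-STS calls into genomic intervals: consecutive deleted STSs
   are connected when the gap is under 100 kb and nothing but deleted or
   non-deleted *multi-copy* STSs lies between them (a non-deleted
   single-copy STS always breaks a run), with inner/outer boundary
   estimates,
5. assigns **Y haplogroups** from a marker-genotype table against an
   editable tree and tests haplogroup–phenotype (one-sided Fisher) and
   haplogroup–deletion (exact binomial) associations,
6. produces **cohort statistics**: per-group deletion summaries,
   chi-square / Kruskal–Wallis contrasts, frequency and recurrence spectra,
   and annotation-category enrichment.

A fully seeded simulator (`stsdel.simulate`) generates catalogs, depth
matrices with planted deletions (recurrent founder blocks tied to a
haplogroup, long case-specific runs, scattered singletons, partial copy loss
at multi-copy sites), haplogroup genotypes and truth labels, so the entire
pipeline is testable offline.

## CLI

One command materializes a demo workspace; the others chain into the full
pipeline:

```sh
stsdel simulate --seed 1 --out demo/
stsdel qc       --depth demo/depth.tsv --out demo/qc.tsv --report demo/qc.json
stsdel features --depth demo/qc.tsv --out demo/features.tsv
stsdel train    --training demo/training.tsv --out demo/model.json   # add --grid to re-search (C, sigma)
stsdel call     --model demo/model.json --features demo/features.tsv --out demo/calls.tsv
stsdel merge    --calls demo/calls.tsv --catalog demo/catalog.tsv --out demo/intervals.bed
stsdel assign   --tree demo/tree.yaml --genotypes demo/genotypes.tsv --out demo/haplogroups.tsv
stsdel assoc    --assignments demo/haplogroups.tsv --metadata demo/metadata.tsv --out demo/assoc.tsv
stsdel summarize --calls demo/calls.tsv --catalog demo/catalog.tsv \
                 --metadata demo/metadata.tsv --out demo/summary.json
```

(`demo/training.tsv` is produced programmatically in tests via
`stsdel.simulate.make_training_subset`; with real data it holds
wet-lab-validated labels: `sample_id  sts_id  f1  f2  f3  deleted`.)

## Layout

| module | role |
| --- | --- |
| `stsdel.catalog` | STS catalog: records, validation, interval queries |
| `stsdel.qc` | depth-matrix filter cascade and QC report |
| `stsdel.features` | the three depth-derived predictors |
| `stsdel.svm` | CV grid search, SVM training, deletion calling |
| `stsdel.merge` | interval merging and unique-deletion census |
| `stsdel.haplogroup` | tree-based assignment and association tests |
| `stsdel.cohort` | group summaries, spectra, enrichment statistics |
| `stsdel.simulate` | seeded synthetic cohorts with truth labels |
| `stsdel.pipeline` | end-to-end drivers and recovery metrics |
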