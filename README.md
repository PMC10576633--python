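# scmulti

Single-cell DNA + protein multiomics analysis for Tapestri-style
multi-assay HDF5 samples. One sample holds three cell-by-feature assays on
a shared set of cell barcodes — DNA variant calls (AF/NGT/GQ/DP layers),
CNV amplicon read counts and antibody (protein) read counts. The package
covers the full downstream workflow:

1. **Read / write** the multi-assay HDF5 layout with strict validation
   (`scmulti.h5_io`), reconciling assays onto one canonical cell order.
2. **QC-filter** variant calls by depth, genotype quality, allele-frequency
   support and cell/variant completeness (`scmulti.dna_variants`).
3. **Identify clones** from the VAF matrix with DBSCAN (auto-estimated
   radius via the k-NN-distance knee, always logged); noise cells get
   label 0 and clones are numbered 1..K by decreasing size.
4. **CNV ploidy**: normalize away per-cell and per-amplicon scale, then
   express copy number relative to a designated diploid reference clone
   (`scmulti.cnv`) — the reference clone sits at ploidy 2 on every amplicon
   by construction.
5. **Protein**: centered log-ratio normalization, 2-D embedding
   (PCA/UMAP/t-SNE) and one-vs-rest clone signatures via Welch t-tests with
   Benjamini–Hochberg adjustment (`scmulti.protein`).
6. **Synthetic data**: a clone-structured generator with full ground truth
   (`scmulti.synthetic_data`), so every stage is testable offline.

## CLI

All stages are exposed through one entry point:

```bash
scmulti simulate --seed 1 --out work/fix          # synthetic fixture + truth sidecars
scmulti summary work/fix.h5                       # dimension/status summary
scmulti filter work/fix.h5 work/filtered.h5       # QC filtering (+ report)
scmulti clones work/filtered.h5 --eps 0.2 --out work/labels.tsv
scmulti cnv work/filtered.h5 --labels work/labels.tsv --reference-clone 1 --out work/ploidy.tsv
scmulti protein work/filtered.h5 --embed pca --out work/embedding.tsv
scmulti signature work/filtered.h5 --labels work/labels.tsv --clone 2 --out work/sig.tsv
scmulti run --config config.yaml                  # the whole pipeline
```

A `run` config (YAML or JSON):

```yaml
input: work/fix.h5
output_prefix: work/run
qc: {min_depth: 10, min_gq: 30, min_af_mutated: 20.0}
cluster: {min_points: 10}        # epsilon omitted -> auto knee estimate
reference_clone: 1
embed_method: pca                # pca | umap | tsne
embed_seed: 42
```

`run` writes the filtered HDF5, a filter report, clone labels, clone-level
ploidy, the 2-D embedding and per-clone signature tables, plus a log that
records every auto-chosen parameter.

## Notes on conventions

- AF is stored in percent (0–100); NGT codes are 0 wild-type, 1 het,
  2 hom-alt, 3 missing.
- Default QC thresholds: DP ≥ 10, GQ ≥ 30, AF ≥ 20% for mutated calls,
  ≥ 50% valid calls per cell and per variant, ≥ 1% mutated fraction per
  variant. All overridable.
- CNV normalization is total-count scaling per cell followed by median
  scaling per amplicon; absolute copy number is therefore only preserved
  for clones whose total copy number matches the diploid total (the usual
  caveat for total-count normalization).
- CLR uses natural log with a +1 pseudocount, per cell across proteins;
  with a pseudocount the transform is *not* scale-invariant.
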