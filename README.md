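# morphmap

A benchmarking toolkit for image-based morphological profiling
(Cell Painting-style) experiments that pair chemical and genetic
perturbations. It implements, as a tested and reusable library, the
full analysis path from well-level profiles to benchmark numbers:

- **Experiment design** — constraint-based 384-well plate maps for a
  compound plate, a CRISPR plate and an ORF plate (edge-aware zone
  constraints, striped solvent controls), the replicate/imaging
  schedule, and leak-free train/validate/test splits.
- **Preprocessing** — median aggregation of single-cell profiles,
  per-plate robust normalization `x' = (x − median)/m.a.d.` against
  negative-control wells (or all wells), redundancy pruning at
  |Pearson r| > 0.9, near-zero-variance removal, and optional
  well-position mean-centering.
- **Retrieval benchmarks** — the central statistic: per-query average
  precision `AP = Σ_k (R_k − R_{k−1}) P_k` over cosine-similarity rank
  lists, permutation p-values against a shared (m, n) null,
  Benjamini–Hochberg q-values, per-class mAP with geometric-mean
  combined q, and the *fraction retrieved* (classes with q < 0.05).
  Three task assemblies: phenotypic-activity calls (replicate
  retrieval vs negative controls), within-modality sister matching,
  and cross-modality gene–compound matching.
- **Directionality** — signed-cosine comparison of same-gene
  cross-modality pairs against the different-gene null, 5th/95th
  percentile tail thresholds, and Fisher's exact test for
  mimic-vs-oppose asymmetry.
- **Synthetic data** — a generator with known ground truth (latent
  gene phenotypes, signed modality couplings, sister sign flips,
  polypharmacology, plate-layout artifacts, inactive fractions) so the
  whole pipeline is testable without any images.

Profile tables are plain delimited text with `Metadata_`-prefixed
metadata columns followed by numeric feature columns — the standard
convention of the field's released datasets.

## Worked example

`examples/phenotypic_activity.py` simulates a compound experiment
(25 genes × 2 compounds, 30% of perturbations inactive), then calls
activity by replicate retrieval:

```
50 compound perturbations evaluated
fraction retrieved = 0.680
34/34 truly active perturbations recovered; 0 false calls
Activity filter kept 34 perturbations for downstream matching
```

`fraction retrieved = 0.680` is the fraction of perturbations whose
replicate wells are retrieved from the negative-control pool
significantly better than chance (combined q < 0.05) — here exactly
the 34 perturbations the generator made active, with no false calls
among the inactive ones. The other scripts in `examples/` walk
through plate design, preprocessing, matching, and directionality the
same way.

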