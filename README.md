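# radrepro

Test–retest reproducibility analysis of radiomics features under a grid of
pre-processing settings, with a synthetic paired-cohort generator so the whole
pipeline is testable without patient data.

The pipeline:

1. **simulate** — generate paired T2W-like lesion volumes (two scans per
   lesion) with a known shared-vs-independent variance structure, anisotropic
   voxels, inter-scan gain/offset drift, per-scan mask jitter, fat/muscle
   reference boxes, and a clinical table (PSAD, prostate volume, PI-RADS,
   ISUP, index-lesion flags).
2. **preprocess** — 48 settings: discretization (FBN 16/32/64/128 or FBS
   5/10/20/40) × signal-intensity normalization (AR dual-reference affine /
   NAR none) × intensity outlier filtering (NoF / IN clip / OUT re-segment at
   μ ± 3σ).
3. **extract** — 107 radiomics features in 7 groups (first-order 18, GLCM 24,
   GLDM 14, GLRLM 16, GLSZM 16, NGTDM 5, 3D shape 14), implemented to the
   reference extraction tool's default conventions (13-direction
   feature-level averaging, 26-connected zones, Chebyshev distance 1,
   marching-cubes mesh).
4. **icc** — ICC(2,1) (two-way random, absolute agreement, single score) per
   feature per setting; features with ICC > 0.75 count as reproducible.
5. **select** — setting with the most reproducible features; ties broken by
   lowest binning value (lowest setting index, with a warning, when binning
   values are incomparable across discretization types).
6. **compare** — Mann–Whitney U / Kruskal–Wallis comparisons of per-category
   ICC distributions and baseline feature values across clinical categories,
   with Benjamini–Hochberg correction per test family.

## CLI

```sh
radrepro simulate --config cohort.yaml --out cohort/ --seed 7
radrepro run --cohort cohort/ --out results/          # extract -> icc -> select -> compare
# or stage by stage:
radrepro extract --cohort cohort/ --out features.csv
radrepro icc --features features.csv --out grid.csv
radrepro select --grid grid.csv --out selected_setting.json
radrepro compare --features features.csv --clinical cohort/clinical.csv \
    --setting selected_setting.json --out comparisons.csv
radrepro preprocess --cohort cohort/ --setting 18 --out roi_stats.csv
```

Cohorts are NIfTI volumes/masks plus `clinical.csv` and `manifest.json`;
feature tables are long-format CSV; the ICC grid is a wide CSV
(features × settings); every run writes a `run_manifest.json`.

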