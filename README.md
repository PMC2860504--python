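# ecmap

Voxel-wise **eigenvector centrality mapping** for 4D functional-imaging time
series in NIfTI-1 format, with degree and (small-ROI) betweenness centrality,
time- and frequency-domain similarity metrics, a group-level statistical
pipeline, and a synthetic-data generator for end-to-end validation.

Given a masked 4D series, every in-mask voxel becomes a node of a weighted
graph whose edge weights are pairwise similarities between voxel time series.
Eigenvector centrality scores each voxel by its entry in the unit-norm
dominant eigenvector of that similarity matrix (power iteration,
Perron–Frobenius uniqueness for irreducible non-negative matrices). For the
scaled-correlation metric the matrix is held in an implicit factored form
`A = (Z Zᵀ + 1 1ᵀ)/2`, so whole-brain problems never materialize the n × n
matrix.

## Features

- **Similarity metrics**
  - scaled linear correlation `(r + 1)/2` (dense or matrix-free factored form)
  - absolute correlation `|r|`
  - lag-window spectral coherence (magnitude-squared) at a chosen frequency,
    with Tukey (default) or Parzen windows; phase coherence is also exposed
- **Centrality**: eigenvector (power iteration), degree (off-diagonal row
  sums), betweenness (Brandes; refuses > 5000 nodes unless `--force`)
- **Group statistics**: rank-based inverse-normal transform
  ("Gaussianization"), voxel-wise paired t-maps, t→z conversion, cluster
  labeling (6/18/26-connectivity), Monte-Carlo cluster-size/cluster-peak
  null distributions, and an OR-rule correction (size or peak exceeds the
  `1 − α/2` null quantile)
- **Synthetic data**: masked 4D series with planted module/hub correlation
  structure and band-limited latent signals, plus paired two-condition
  cohorts with a controllable effect region

## Command line

All randomness is controlled by `--seed`; every output gets a
`<output>.manifest.json` sidecar recording the command, resolved parameters,
input digests, package version, and timestamps.

```bash
# synthetic fixture
ecm synth --out bold.nii --labels labels.nii --mask-out mask.nii --seed 1

# eigenvector centrality map (scaled correlation, matrix-free)
ecm map --bold bold.nii --mask mask.nii --out ecm.nii \
        --metric scaled-corr --method eigenvector

# coherence-based map at 0.1 Hz
ecm map --bold bold.nii --mask mask.nii --out ecm01.nii \
        --metric coherence --freq 0.1 --window tukey

# betweenness on a small ROI
ecm betweenness --bold bold.nii --mask mask.nii --out btw.nii \
        --edge-threshold 0.6 --weighting distance

# paired group contrast with Monte-Carlo cluster correction
ecm group-ttest --group-a subA1.nii --group-a subA2.nii \
                --group-b subB1.nii --group-b subB2.nii \
                --mask mask.nii --paired --z-threshold 2.33 --alpha 0.05 \
                --mc-iters 1000 --fwhm-mm 8 --seed 1 \
                --out-z zmap.nii --out-clusters clusters.tsv
```

The cluster table is TSV with columns
`tail, label, size_voxels, size_mm3, peak_value, peak_x, peak_y, peak_z,
significant`.

## Conventions worth knowing

- In-mask voxels are ordered by ascending linear index with x varying
  fastest; maps are written as float32 with zeros outside the mask.
- Zero-variance or non-finite voxels are dropped from the mask at load time
  (correlation is undefined there); the count is logged.
- Coherence is the **magnitude-squared** form `(c² + q²)/(f_xx f_yy)`.
- Default lag count `M = round(2√T)`, clamped to `[T/10, T/3]`.
- Positive and negative tails of a contrast are corrected independently.

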