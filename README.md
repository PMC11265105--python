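# spatialcoloc

Spatial co-localization analysis for spot-resolved transcriptomics lattices
and two-channel fluorescence images:

- **spot_scoring** — per-spot, per-cell-type enrichment scores (rank-based
  running-sum over marker gene sets) and strict top-quartile positivity
  calls, with ties-at-threshold handled strictly.
- **spatial_joincount** — spatial dependency between cell-type pairs via
  join counts: co-positive spots resolved by coordinate parity
  (`x + y` even/odd), rook or queen adjacency, permutation and closed-form
  nonfree-sampling nulls, z-scores with a default significance cutoff of
  `|z| >= 3`.
- **image_mcc** — Manders colocalization coefficients M1/M2
  (intensity-weighted, masked) with Otsu or fixed thresholding, percentage
  rendering, and grouped time-course summaries.
- **synthgen** — synthetic lattices, abundance fields
  (aggregated/dispersed/random), negative-binomial count matrices, and
  two-channel image pairs with exactly known ground-truth overlap, so every
  stage is testable by parameter recovery or exact enumeration.
- **pipeline** — config-driven orchestration, file I/O (MTX triplet, CSV,
  GMT, TIFF/PNG), and JSON run reports.

## CLI

```sh
# end-to-end demo on generated data (writes inputs + all outputs)
spatialcoloc demo --outdir out/demo --seed 1

# spot scoring + positivity + pairwise join counts from files
spatialcoloc spatial --config cfg.yaml

# Manders coefficients for a manifest of image pairs
spatialcoloc mcc --config cfg.yaml
```

Exit codes: 0 success, 1 validation error, 2 partial failure (some images
unreadable). A `spatial` config looks like:

```yaml
mode: spatial
output_dir: out/run1
seeds: {run: 1, joincount: 2}
inputs:
  expression: expr.csv        # or an MTX triplet directory
  coords: coords.csv          # spot_id,x,y
  gene_sets: markers.gmt
scoring: {alpha: 0.25, quantile: 0.75}
joincount: {scheme: rook, n_perm: 999, z_cutoff: 3.0}
```

Coordinates are normalized to a 0-based origin; the applied offset is
logged and recorded in the run report because shifting either axis by one
flips every parity assignment.

## Notes

- The positivity rule is strict (`score > threshold`) with a nearest-rank
  quantile, so all-tied scores yield zero positives.
- A join-count null with zero variance (e.g. a 1x2 lattice) is reported as
  not-computable, never as z = 0.
- Manders coefficients with a zero denominator are reported as
  not-computable rather than 0.
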