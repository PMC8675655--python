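# discquant

Quantification toolkit for cell-competition imaging experiments in the
*Drosophila* wing disc: 3D clone segmentation in multichannel confocal
z-stacks, border/center clone-territory decomposition, volume-normalized
apoptosis density, pouch coverage, posterior/anterior compartment intensity
ratios, ubiquitin-speckle density, ribosomal SSU/LSU stoichiometry
summaries from proteomics tables, and the exact nonparametric statistics
that tie disc cohorts together.  A synthetic wing-disc generator with exact
ground truth makes the entire chain testable without microscope data.

## Who this is for

Labs that quantify mosaic or compartment-driven wing-disc experiments:
GFP-marked clones immunostained for an apoptosis marker (cleaved dcp1),
stress reporters (p-eIF2α, GstD1-GFP, p62) expressed or stained across the
anterior/posterior boundary, and puncta-forming markers (FK2).  Each
wing disc (or disc compartment) is one statistical unit; cohorts are
compared with the Wilcoxon matched-pairs signed-rank test (paired,
within-disc designs), its one-sample form (ratios against 1), or the
Mann–Whitney U-test (between genotypes).  No multiple-comparison
correction is applied.

## The core measurements

Given a stack with channels for nuclei, a GFP clone marker, stains and a
death marker (axis order `(C, Z, Y, X)`, voxel size `(dz, dy, dx)` µm):

- **Clone patches** — Gaussian smoothing (µm, anisotropy-aware), Otsu
  threshold computed inside the pouch ROI, 26-connected 3D components,
  minimum-volume filter.
- **Border vs center** — for each clone, the *border* is every voxel within
  `n × cell_diameter` (default n = 2) of the clone perimeter, by a
  per-z-section Euclidean distance transform; the *center* is the rest.
  Border ⊎ center = clone, exactly.
- **Death density** — `100 × |dcp1 ∩ territory| / |territory|`, i.e. the
  percentage of each territory's *volume* that is death-marker positive;
  border and center of the same disc form one paired observation.
- **Pouch coverage** — percentage of pouch volume occupied by clones.
- **P/A ratio** — posterior / anterior mean intensity of a channel over
  user-supplied (or midline) compartment masks.
- **Speckle density** — multiscale Laplacian-of-Gaussian puncta detection,
  counts per 1000 µm³.
- **SSU/LSU imbalance** — per-class mean log2 fold change with Student-t
  95% CI, one-sample Wilcoxon vs 0, and Mann–Whitney SSU vs LSU.

Exact null distributions are enumerated for the signed-rank test (n ≤ 15)
and the U-test (n₁+n₂ ≤ 12, no ties); larger or tied samples use the
tie-corrected normal approximation, and the method used is always recorded.

## Worked example

Simulate a six-disc mosaic cohort in which the clone border truly dies at
twice the center rate (10% vs 5% of territory volume, 20% disc-to-disc
jitter), then run the full pipeline:

```python
from discquant import SimConfig, simulate_cohort, run_mosaic_pipeline

cfg = SimConfig(seed=7, channels=("gfp", "death"), noise_sd=5.0)
discs = [
    (f"disc{i}", stack, truth.pouch_mask)
    for i, (stack, truth) in enumerate(simulate_cohort(cfg, n_discs=6, per_disc_jitter=0.2))
]
table = run_mosaic_pipeline(discs, cell_diameter=5.0)
```

The long-format results table pivots to:

```
metric  coverage_pct death_density_pct
scope          pouch            border center exterior_wt
disc0          29.86              9.61   4.66        2.13
disc1          29.82              9.92   4.87        2.02
disc2          29.79              9.29   5.39        1.98
disc3          29.87              6.93   5.50        1.86
disc4          29.77              7.82   5.46        2.93
disc5          29.86              9.97   5.31        1.79

paired Wilcoxon border vs center: W=21.0, p=0.03125 (exact)
```

Coverage is recovered at the generated 30%; border death exceeds center
death in every disc, and with all six paired differences positive the
two-sided exact signed-rank p-value is 2/2⁶ = 0.03125 — elevated death at
the clone border is the imaging signature of cell competition.

The same stages are available from the shell:

```bash
discquant simulate cohort --n-discs 13 --seed 1 --out-dir cohort/
discquant quantify mosaic --stack cohort/disc_000/stack.tif \
    --roi cohort/disc_000/pouch_mask.tif --cell-diameter 5 --out-dir results/
discquant proteome proteome.csv
discquant stats mannwhitney --x 1,2,3 --y 4,5,6
```

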