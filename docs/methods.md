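# Methods

## Measurement model

All quantities are derived from voxel sets on a regular grid with physical
spacing `(dz, dy, dx)` in µm (z-step 1 µm by default, matching standard
confocal acquisition of wing discs; the in-plane pixel size is a free
parameter, 1 µm in the synthetic defaults).  A voxel is in or out of a
mask; there is no sub-voxel geometry.  All analysis is restricted to the
pouch region of interest, and intensity metrics are means over all mask
voxels across z-sections (full-volume means, not maximum projections) —
consistent with the volume-based normalization of the death readout.  The
choice of volume means over projections is a convention; it is recorded on
every output row via the `scope` field.

### Segmentation

Clone patches and death-marker regions share one operator: Gaussian
smoothing with a physical sigma converted per axis (so dz ≠ dx is handled
correctly), an automatic Otsu threshold computed **from ROI voxels only**,
and 26-connected 3D components.  Otsu-within-ROI is parameter-free and
shift-equivariant (adding a constant to a channel does not change the
mask); a fixed absolute threshold or an intensity percentile can be
substituted where the automatic choice is unsuitable.  Defaults: 1.0 µm
smoothing for clone patches (clone-scale objects), 0.5 µm for the death
channel — apoptotic puncta are nuclear-scale, and heavier smoothing
measurably inflates their thresholded volume.  Components smaller than one
nuclear volume (π d³/6 at the estimated cell diameter) are discarded by
default, which removes debris while keeping single-cell clones.

### Border / center territories

The border of a clone is every clone voxel within `n_cell_diameters ×
cell_diameter` (default 2 cell diameters) of the clone perimeter; the
center is the remainder.  The distance is the Euclidean distance transform
computed **per z-section** with the true in-plane spacing — section-wise
processing matches how such masks are produced in practice and avoids
anisotropy artifacts at a 1 µm z-step; a full-3D mode is available behind
`mode="3d"`.  Each labeled patch is decomposed independently within a
bounding box padded by the band width (so touching neighbors are seen as
perimeter, and borders of nearby patches never merge).  The decomposition
is an exact partition: border ⊎ center = clone on every input, and patches
thinner than the band have empty centers (such discs are flagged and
excluded from paired tests).

The cell diameter is either supplied or estimated from the nuclei channel:
nuclei on a central band of sections are segmented (smooth → Otsu →
watershed split of touching nuclei) and the median equivalent-circle
diameter of the cross-sections is returned.  The median planar
cross-section of a sphere of diameter D is (√3/2) D ≈ 0.87 D, so the
estimate is geometry-biased low by ~13%; this is within the tolerance the
border band needs.  Fewer than 20 cross-sections triggers a fallback to
the configured default (5 µm) with a warning.

### Speckle detection

Puncta are detected per z-section by scale-normalized
Laplacian-of-Gaussian filtering over the configured physical diameter
range (sigma = r/√2; sub-pixel sigmas are clamped to 1 px, where discrete
LoG kernels become unstable), peak extraction at a relative response
threshold on [0,1]-rescaled intensities, then 3D de-duplication: the
weaker of any two detections closer than the minimum diameter is dropped,
with axial distances divided by an elongation factor (default 3) because
the confocal point-spread function extends one physical punctum across
~3 sections.

### Statistics

Cohort comparisons use the Wilcoxon matched-pairs signed-rank test (paired
designs: border vs center of the same disc, posterior vs anterior of the
same disc), the one-sample signed-rank test (P/A ratios against 1), and
the Mann–Whitney U-test (between genotypes).  Small-sample null
distributions are computed exactly — by the subset-sum recurrence over all
2ⁿ sign assignments (signed rank, n ≤ 15) and the two-group rank-split
recurrence over all C(n₁+n₂, n₁) splits (U-test, n₁+n₂ ≤ 12) — with
two-sided p = min(1, 2·min(P≤, P≥)).  Zero differences are dropped and
counted; ties take midranks; the exact path refuses tied ranks and falls
through to the tie-corrected normal approximation (no continuity
correction).  The method actually used is recorded on every result.  No
multiplicity correction is applied anywhere.  Confidence intervals on
means are Student-t.

## Synthetic data: what it emulates, and what it does not

The generator renders an ellipsoidal pouch (default semi-axes 7 × 62 ×
72 µm in a 16 × 160 × 160 grid) with up to five channels: nuclei (packed
5 µm spheres), GFP clones, a graded reporter, speckles, and a death
marker.  Intensities are `signal·mask + background + Gaussian noise`,
clipped at zero (defaults 100/20/5).  Specific choices:

- **Clones** are unions of overlapping in-plane disks (radius 2.5 cell
  diameters, growth biased toward the patch seed so footprints stay
  compact with irregular outlines), extruded through the pouch thickness —
  clones span the epithelium, so their footprint, not a 3D ball union,
  is the right shape model.  Growth stops exactly at the target coverage
  (the last disk is trimmed inside-out; overshoot is at most one pouch
  column).  Defaults: 3 patches, 30% coverage.
- **Death** is placed as ~one-nuclear-volume balls at uniformly random
  territory voxels, clipped to the territory, until the territory's target
  volume fraction is reached exactly (final ball trimmed).  Defaults:
  border 10%, center 5%, wild-type 2% — a two-fold border/center death
  ratio, the competition signature the pipeline is designed to detect.
- **Reporter**: posterior pouch voxels are exactly `fold ×` the anterior
  level before noise, so the true P/A ratio is the configured fold
  (default 1.8); background applies only outside the pouch, because P/A
  ratios are offset-sensitive and the truth must be well-defined.
- **Speckles** are anisotropic Gaussian spots (σ = 0.6 µm in-plane, 1 µm
  axially) at Poisson-disc positions (≥ 4 µm apart), count = density ×
  pouch volume / 1000.
- **Cohorts** derive disc i's seed as `base + i`; disc-to-disc biological
  variability is a mean-one log-normal factor (relative sd =
  `per_disc_jitter`) applied independently to each effect parameter.

Not modeled: point-spread-function optics, autofluorescence gradients,
clone growth/competition dynamics, cell extrusion, intensity bleaching.
Consequently, passing recovery tests demonstrates that the measurement
chain is unbiased and calibrated on geometrically realistic masks with
additive noise — not that segmentation is robust to the texture,
anisotropic blur, or spatially varying background of real confocal data;
on real data the threshold overrides and per-disc logs exist precisely to
audit those effects.

## Calibration results the tests compute

- An in-plane disk clone of radius 50 µm with a 20 µm band has an analytic
  border volume fraction of (50²−30²)/50² = 64%; the decomposition
  reproduces it within discretization (±3 points).
- Noise-free full-pipeline death recovery is compared at 3 standard errors
  of the blob placement process, defined as s.e. = 100·√(p(1−p)·v_blob/V),
  the binomial-at-blob-granularity scale (v_blob = one nuclear volume, V =
  territory volume).  Recovered border density is within ±0.4 points of
  truth; center density runs up to ~2 points high because perimeter
  smoothing during segmentation reassigns a thin shell of true border
  (which dies more) into the recovered center — a real property of
  smoothed-mask territory analysis worth knowing when interpreting small
  center territories.
- Simulated 13-disc cohorts with a two-fold border/center death ratio and
  20% jitter are detected by the paired exact Wilcoxon in ~100% of 200
  runs; with equal rates everywhere the rejection rate is ~0.05, i.e. the
  pipeline adds no directional bias to the test's exact size.
- Ten-disc compartment cohorts at fold 1.8 and study noise recover the
  median ratio within 10%; at fold 1.0 the one-sample test vs 1 is
  non-significant in ~94% of runs.
- Proteomics tables at the detected-protein counts (29 SSU, 49 LSU; class
  means −0.35/+0.15, sd 0.2) give class-mean CIs with ~94% empirical
  coverage and a Mann–Whitney SSU-vs-LSU rejection rate of ~100%; the
  t-CI has 93–97% coverage over 2000 Gaussian replicates.

Problem sizes in the acceptance script (compact 10 × 90 × 90 discs for the
200-cohort power/size runs, full-size discs elsewhere) were chosen so the
whole battery runs in a few minutes on one CPU while keeping every
territory large enough to hold several death blobs.

## Numerical and edge-case conventions

- Flat (zero-variance) channels segment to empty masks rather than error.
- Empty territories yield NaN densities, are flagged in the results table,
  and are excluded from paired tests; cohorts with fewer than two usable
  pairs emit a test row flagged `insufficient n`.
- Degenerate statistics inputs (all differences zero, all pooled values
  identical) raise informative errors at the stats layer; the proteomics
  summarizer converts them to NaN p-values so a degenerate class does not
  abort a whole summary.
- Masks at the image boundary have no perimeter there (the distance
  transform sees only in-grid complement); the pouch ROI keeps real
  patches away from grid edges.
- Results CSVs are written with a fixed column order and `%.10g` floats,
  making end-to-end runs byte-reproducible for identical inputs.

## Known limitations

- Compartment masks must be supplied (or taken as the pouch midline in
  simulations); inferring the anterior/posterior boundary from a marker
  channel is out of scope.
- The estimator of cell diameter assumes roughly spherical, moderately
  packed nuclei; columnar pseudostratified nuclei will bias it.
- Exact U-test enumeration refuses ties entirely rather than enumerating
  the conditional distribution given the tie pattern.
- The P/A ratio is not invariant to additive background; an optional
  per-slice background subtraction exists but is off by default because
  the raw-intensity convention is the one being reproduced.
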