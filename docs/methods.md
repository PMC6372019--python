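# Methods

## Scope and model

`cytoconn` implements a two-scale analysis: microscale cortical
cytoarchitecture, summarized as 1,000-sample laminar intensity profiles
from cell-body-stained section images, is related to the macroscale
structural connectome, summarized as group consensus networks of
streamline counts and their nodal graph metrics. Because the original data
sources (an ultrahigh-resolution histological reconstruction and a
multi-hundred-subject diffusion-MRI cohort) are terabyte-scale, the
package ships a first-class synthetic-data module that generates every
input with known ground truth; all quantitative claims the test suite
makes are claims about recovery of planted structure, plus exact checks of
the procedural constants of the method itself.

## Profile extraction

A profile is extracted for a pial/white-matter point pair and its
nearest-neighbor pair (nearest by Euclidean distance between segment
midpoints — the midpoint convention is symmetric in the two surfaces and
robust to thickness differences; ties break to the lowest pair id). The
quadrilateral (pair.pial, neighbor.pial, neighbor.wm, pair.wm) is treated
as the image of the unit square under the bilinear interpolation of its
corners; the depth coordinate v is partitioned into 1,000 strata. Each
stratum is sampled on a lattice of 4 columns across the quadrilateral and
enough depth rows that strata thicker than one pixel are subsampled, with
bilinear image interpolation; a stratum's value is the lattice mean. The
"block" shape (full-width depth strata rather than sub-columns) is an
assumption; it is resolution independent and exactly checkable: on a
linear intensity gradient bilinear sampling is exact, and the tests pin
stratum k to the gradient at depth (k+0.5)/1000 to 1e-9.

Region assignment uses the labeled pixel nearest to the segment midpoint
(ties: lowest region id, then lowest raster index). Quality control is a
fixed two-step order: (1) profiles whose midpoint-to-labeled-pixel
distance exceeds Q3 + 1.5·IQR (quartiles by linear interpolation, type 7;
one-sided upper rule, since only "too far" profiles are suspect) are
dropped; (2) profiles whose neighbor pair sits in a different region are
dropped as boundary-crossers. Regions with fewer than `min_count = 20`
profiles are kept in the outputs but flagged excluded; thresholds 0 and 50
are exercised in tests and produce nested included-region sets.

## Similarity and the rank transform

The similarity matrix holds Pearson correlations between regional mean
profiles (excluded regions masked with NaN). The rank-matched normal
transform replaces the off-diagonal upper-triangle values by standard
normal quantiles at plotting positions (rank − 0.5)/n (average ranks on
ties — ties are not documented in the source procedure, so the average
convention was chosen), then rescales affinely so the output sample mean
and SD are exactly 1 and 0.2; the result is mirrored to preserve symmetry.
The transform is monotone (rank preserving) and idempotent up to the
affine rescale. The same transform is applied to consensus-edge streamline
counts. Raw (untransformed) similarity remains available
(`transform_state == "raw"`).

## Tractography

The tracker is a voxel-hopping FACT variant: directions are axial unit
vectors per voxel; 8 seeds per voxel sit on a fixed 2×2×2 subvoxel grid
(offsets ±0.25 voxel — the seed count is specified by the method, the
placement is not, and a fixed grid keeps tracking deterministic). From
each seed two half-tracks are stepped at 0.5 voxel per step along the
current voxel's direction, sign-aligned with the travel direction, and
concatenated. A step is refused — terminating the streamline — when the
next voxel has FA < 0.1, leaves the mask/grid, or its (sign-aligned)
direction deviates from the current one by more than 45°; the comparison
is done on cosines with a 1e-12 guard so an exactly-45° bend passes, and a
scan of bend angles 30°–60° recovers 45° as the largest traversable angle.
Streamline endpoints (not traversed voxels) define the connected region
pair; NOS is symmetric with zero diagonal. Streamline density divides NOS
by the mean volume of the two endpoint regions.

The group binary network keeps edges with weight > 0 in **strictly more
than** a threshold fraction of subjects (default 0.5; 0.4/0.6 give nested
edge sets); the group weight is the mean over the subjects with a nonzero
weight, not over all subjects.

## Graph metrics

Degree and strength are binary/weighted row sums. Betweenness is the
ordered-pair fraction of shortest paths through a node, normalized by
(N−1)(N−2); because raw values are heavily right-skewed they are reported
alongside ln(b + ε) with ε = 1/((N−1)(N−2)), the scale of the smallest
attainable nonzero value, which keeps zero-betweenness nodes finite.
Shortest paths are **hop counts on the binary consensus topology even for
the weighted network** — that is the printed definition of path length in
the source method — so strength is the only weight-using nodal metric; a
1/weight distance mode is exposed behind a flag for sensitivity analysis.
Disconnected graphs raise an error rather than returning partial results.
The implementations are thin wrappers over networkx; the test suite checks
them against independent matrix-power path-enumeration oracles on every
connected graph of ≤ 6 nodes and on random 8-node graphs.

## Statistics

All tests return a `StatResult` and significance is decided only after
Benjamini–Hochberg FDR (q < 0.05) across the declared 28-test family
(configured, not hard-coded, in `PipelineConfig.test_family`). The family
reconstruction — edge t test; NOS and density correlations; distance
ANOVA + 3 post hocs; 3 per-bin correlations; residualized t test and
correlation; 3 hemisphere t tests and 3 hemisphere correlations; 2 nodal
strength correlations, nodal degree correlation, 2 partial correlations,
residualized nodal correlation; betweenness / clustering / path-length
correlations; and the strength coefficient of the 4-predictor multiple
regression — totals 28; only the strength coefficient of the regression
enters the family, the other three coefficients are reported uncorrected.

Conventions: the two-sample t test is pooled-variance (Student), df =
n1+n2−2, matching the integer degrees of freedom the method reports;
partial correlation correlates the residuals of both variables on the
covariates (with intercept), p from t on n−2−k df; one-way ANOVA reports
both df (k−1, N−k). Distance categories rank the centroid Euclidean
distances among *connected* pairs: lowest ⌈E/4⌉ are short-range, highest
⌈E/4⌉ long-range, the rest mid-range, ties resolved by stable input
order. Residualization regresses distance, mean pair volume and mean pair
surface area (with intercept) out of both similarity and weight.

## Synthetic data: what it emulates and what it does not

- **Sections** are circular annuli (pial = outer circle, WM = inner
  circle) with regions as angular sectors: perpendiculars and depths have
  closed forms, so extraction oracles are exact. Pixel intensity equals
  the region's truth curve at the pixel's radial depth plus i.i.d.
  Gaussian noise; a thin continuation band beyond both surfaces carries
  the curve end values, since stain does not vanish at the anatomical
  boundary. Intensities are in arbitrary [0, 1] units (only correlations
  matter downstream); the digitization polarity is configurable
  (`dark_stain_high`) because the convention is not fixed by the method.
- **Truth curves** are a shared base laminar curve plus region-specific
  sine-series deviations whose coefficients drift smoothly along the
  ribbon, scaled by a per-region differentiation factor. The factor is
  what plants *nodal*-level structure: weakly differentiated regions are
  similar to most of the cortex, giving the mean-similarity map real
  variance — without it, the similarity matrix is near-circulant and every
  region has the same mean similarity.
- **Point pairs** are radial (hence exactly perpendicular), sampled in
  along-ribbon groups of four with short intervals, in several independent
  section batches, mirroring manual selection of a few pairs at a time on
  many sections; coincident pairs from overlapping groups produce
  zero-area quadrilaterals and are skipped with bookkeeping.
- **Cohorts** use a two-level edge model: a group-level indicator drawn
  once per pair with probability expit(logit(base_density) + β·sim), and
  per-subject expression with probability 0.8 — the two levels make the
  >50% consensus rule non-trivial. Present edges get integer counts
  round(max(0, 20 + β·sim + N(0, 5))). Defaults: 60 regions, 30 subjects,
  β = 2, base density 0.25 (a typical group-network density at this
  parcellation scale). Under β = 0 the connected/nonconnected t test is
  calibrated (≈ 5% rejections); under β = 2 the positive edge effect and
  the positive similarity–strength correlation are recovered in ≥ 95% of
  replicates.
- **Not emulated:** 3-D histology, cortical folding, histological
  artifacts, realistic diffusion signal (no b-vectors or q-space
  reconstruction), registration error, inter-subject anatomical
  variability. Passing tests therefore demonstrate correctness of the
  *procedure* and recoverability of planted couplings, not performance on
  real histology/MRI.

## Replicate studies and problem sizes

Calibration and power replicates (`run_planted`) feed the truth curves
directly into the similarity stage: re-rendering and re-extracting the
section image per replicate would repeat a deterministic step whose
fidelity is established separately (noise-free recovery of truth profiles
at r > 0.99). Power uses 100 replicates of the 60-region / 30-subject
condition with the full 28-test family; null calibration uses 500
replicates of the edge t test at α = 0.05. The end-to-end image-based run
uses 28 pairs per region across ~4 section batches (≈ 1,700 pairs),
enough that most regions clear the 20-profile threshold while a few fall
below it, exercising the exclusion path.

## Known limitations and open choices

- The tractography step length (0.5 voxel) and seed placement are
  conventions, exposed as parameters; only the seed count, FA cutoff and
  turn threshold are fixed by the method.
- The 28-test family composition is a reconstruction; it is declared in
  configuration so alternative family definitions can be tested.
- The edge t test's degrees of freedom depend on the pair universe after
  region exclusions; the pipeline logs its pair count and df rather than
  forcing any particular value.
- ANOVA reports both degrees of freedom; single-df summaries of an F
  statistic are not reproduced.
- The layer-table validation (`validate_ek`) checks self-consistency on
  synthetic data (step profiles built from the same truth curves); it is
  not a substitute for agreement with a real cytoarchitectonic atlas.
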