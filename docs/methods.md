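# Methods

This note documents the models, conventions and numerical choices behind
`tickniche`, and what the synthetic test beds do and do not establish about
real data.

## Record curation

Records arrive as UTF-8 comma-separated text (decimal-point coordinates,
WGS84).  Inclusion requires (i) a species-level name on the accepted-names
list or a defined group label, and (ii) an unambiguous locality —
`coordinates` or `unambiguous_name`.  Rejection rules are checked in a fixed
order (locality quality, then name, then geography) and tallied per rule;
because at most one rule fires per record, rejected + retained always equals
the input size and filtering is idempotent.  Temporal fields never gate
inclusion: most compiled records lack a collection year, and dropping them
would discard the bulk of the signal.

The study window is the closed box 11°W–45°E × 29°N–71°N.  Membership
exceptions are driven by *region tags*, not geometry: the Canary Islands lie
south of the box yet belong to the surveyed territory, while Iceland and the
Azores are excluded regardless of coordinates.  Tags were chosen over
polygons because the exceptions are political/biogeographic, not geometric.

Name harmonization is a pure lookup: synonym table first, then the
accepted-names list; unknown names are returned flagged, never silently
passed.  *R. sanguineus* and *R. turanicus* collapse to the
*R. sanguineus* group label at harmonization time (the literature cannot
reliably separate them), with the raw name preserved for audit.
Table percentages are rounded half-up to one decimal, the convention of the
published count tables this output mirrors.

## Environmental attachment

Rasters use a plain-text single-band dialect (header + rows, cell-center
registered, northernmost row first) so the pipeline has no geo-library
dependency; co-registration (shape, origin, cell size) is enforced when a
stack is assembled, and the offending layer is named on failure.

Attachment is nearest-cell-center lookup, not interpolation: at ~5-km
monthly products the cell value *is* the observation.  "Nearest" is planar
in degrees; within a mid-latitude window the anisotropy between degrees of
longitude and latitude can displace the chosen cell only when a point falls
near a cell boundary, an error bounded by one cell and irrelevant at the
resolution of the analysis.  Ties break toward the lower (row, column)
index via half-down rounding of the fractional index.  Points on nodata
cells yield incomplete vectors; incomplete vectors are excluded from
ordination by default.

## Climate space

The 24 monthly LST/NDVI variables are reduced by PCA of the **correlation**
matrix — LST and NDVI have incommensurable units, so covariance PCA would
let temperature variance dominate.  The eigendecomposition is
`numpy.linalg.eigh` of the explicit correlation matrix; tiny negative
eigenvalues from floating point are clipped to zero.  Axis signs are
arbitrary, so each axis is oriented with its largest-magnitude loading
positive; downstream comparisons therefore use |r| where sign is
convention.  Default retained dimensionality is 3, with 2 supported for
plotting and fast overlap analysis.

The space is fitted on the **background** (all valid cells, optionally
subsampled with a fixed seed); occurrences are projected, never used to
fit.  This keeps the availability density and every species' scores in one
common frame and matches standard environmental-niche ordination practice.
Axis interpretation is descriptive: Pearson correlations of axis scores
with annual mean LST, annual LST range and annual mean NDVI are reported
with sign, and a degenerate derived variable yields NaN rather than a
silent drop.

## Occupancy densities and Schoener's D

The retained axes are partitioned into r bins per axis (default r = 100,
d = 2 by default for speed and plotting; d = 3 supported).  Bounds are the
pooled background+occurrence range expanded by a 5 % margin; bins are
half-open with the last bin closed, so assignment is a partition.

Densities are product-Gaussian kernel mixtures evaluated at cell centers
and renormalized to unit mass on the grid.  Because the kernel is
separable, the d-dimensional evaluation is a per-axis matrix contraction
(an `n_points × r` Gaussian matrix per axis, combined by matmul/einsum),
which keeps r = 100 grids cheap inside permutation loops.  Bandwidths
follow Silverman's d-dimensional rule per axis on the sample being
smoothed, times a configurable multiplier (default 1), floored at 1e-12.

Occupancy is `z ∝ o/e` on cells whose availability exceeds a mass floor of
1e-12 of total background mass (uninhabitable cells get z = 0), then
renormalized; with correction off, `z = o` exactly.  Correction is on by
default — raw occurrence density confounds niche use with how common a
climate is — but the flag matters for oracle tests (below).

Schoener's D is `1 − ½ Σ|z₁ − z₂|`, clipped into [0, 1] against floating
point.  The equivalency test pools the two score sets, re-partitions at
random into the original sample sizes (without replacement), and recomputes
the **full** pipeline per replicate — including per-sample Silverman
bandwidths — on a grid and availability density fixed by the pooled inputs
(permutation cannot change which climates exist).  The p-value uses the
add-one convention, one-sided lower tail: equivalency is rejected when the
observed niches are less similar than random reallocation produces.  With
N = 99 the minimum attainable p is 0.01.

## Habitat classification

k-means (k-means++ initialization, best of 10 restarts by within-cluster
sum of squares, fixed seed) on per-column-standardized 24-month seasonal
profiles; scikit-learn's KMeans provides the algorithm, including its
empty-cluster relocation.  k has no defensible default on real territories
and must be given explicitly on the CLI.  Whether the original habitat
classifications standardized features is unknowable from their outputs;
standardization is this package's documented choice, for the same
unit-incommensurability reason as the correlation PCA.  Category statistics
report per-(category, variable, month) mean and population SD.

## Hexagonal summaries

Pointy-top hexagons in axial coordinates on the lon/lat plane; "0.5°
resolution" is read as the horizontal center-to-center spacing
(circumradius = spacing/√3).  Point assignment is the fractional axial
transform plus cube rounding; edge ties resolve deterministically through
round-half-to-even.  The planar treatment is a display-scale approximation,
consistent with the attachment step.

## Synthetic data

`simulate_raster_stack` builds each monthly layer as a linear spatial
surface plus a sinusoidal seasonal term
`amplitude · cos(2π(m − phase)/12)` plus i.i.d. Gaussian noise.  Defaults
emulate a Mediterranean-to-boreal window: LST base 22 °C with a −0.45 °C
per-degree-latitude gradient and a 10 °C seasonal amplitude peaking in
July; NDVI base 0.45, mild opposite gradients, amplitude 0.15 peaking in
May; noise SDs 0.5 °C and 0.01.

`simulate_occurrences` samples cells with probability proportional to a
Gaussian niche density evaluated at each cell's environmental vector
(optionally times a spatial bias field), jitters coordinates uniformly
within the source cell, and injects metadata: hosts at rate 0.6 from a
small resolvable list, stages at 0.7/0.2/0.1 adult/nymph/larva (adults
dominate published records), and curation defects at configured per-record
rates.  Defects are mutually exclusive per record, so the injected ledger
maps one-to-one onto filter rules and the filter tally can be required to
match it exactly.  Niches can instead be specified directly on climate-space
axes and sampled with `sample_niche_scores`; for two equal isotropic
Gaussians separated by δ the true overlap is D = 2Φ(−δ/(2σ)), and
`true_schoener_d` computes D for arbitrary 2-D Gaussian pairs by dense
numeric integration (400² grid over ±6 SD).

What the generator does **not** emulate: spatial autocorrelation beyond a
linear trend, literature reporting bias structure, identification error,
multi-species records, or temporal incoherence between record dates and
raster epochs.  Passing tests therefore establish the *computational*
correctness and calibration of the pipeline, not the ecological validity of
any particular real-data result.

## Verification sizes and expectations

The oracle suite runs D-recovery at 2,000 records per species on r = 100
grids against numerically integrated truth (observed absolute errors are
about 0.01–0.02, against a ±0.05 acceptance band), and the equivalency
calibration at 200 repetitions of n = 30 + 30 with N = 99 permutations
(the permutation test is exact under exchangeability, so the rejection rate
at α = 0.05 is binomial around 0.05).  D-recovery runs with availability
correction off because the integrated truth is the overlap of the
generating densities themselves; with a uniform background the two routes
coincide up to discretization.

## Known limitations

* Planar-degree distances in attachment and hexagon assignment (documented
  approximations, not configurable).
* The availability correction divides by a smoothed background density;
  with very small background samples the ratio is noisy at the climate
  space's edges.  Use the background-subsample seed and the bandwidth
  multiplier to probe sensitivity.
* `true_schoener_d` covers 2-D Gaussian niches only; 3-D pipeline runs are
  supported but their oracle tests reduce to direct-summation identities.
* The equivalency test's permutation loop is serial; at N ≫ 1000 with
  d = 3 and r = 100 it becomes minutes-scale.
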