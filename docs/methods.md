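# Methods

This note documents the models, parameter choices and numerical conventions
behind `isletmito`, and what the synthetic validation does and does not
demonstrate about real data.

## Coordinate and raster conventions

All modules share one convention: 0-based pixel indices, polygon vertices in
pixel units with x = column and y = row, pixel centers at integer
coordinates, physical lengths = pixel lengths × `pixel_size_um`. A pixel
belongs to a polygon iff its center is inside by the even-odd rule, with
boundary-center ties counted as inside. Mask-to-polygon tracing
(`annotations_from_labels`) places vertices on pixel corners, so
polygonize→rasterize is exact. Neither microscope pixel size is assumed:
pixel size is a required input with no default when metadata lacks it.

## Motility quantifier

**Estimator.** The per-pixel temporal SD uses the sample convention
(denominator T−1), matching the common z-projection default; the choice is
recorded in every results table's metadata. The temporal mean image is
always computed alongside as the bleaching/membrane-potential control; no
detrending is applied. Per cell, the Pearson correlation between SD and
mean over the cell mask is reported (`qc_sd_mean_r`); cells with |r| above
a configurable cutoff (default 0.7) are flagged in `qc_sd_vs_mean` as
possibly intensity-artefact-driven. Note that shot noise alone induces a
positive SD–mean correlation, so the flag is a screen, not a verdict.

**Normalization.** The SD image is divided by its maximum over the whole
cell mask, nucleus included (a `line_restricted` max over sampled rays only
is deliberately not the default; the cell-wide maximum is the cell's
"maximal motility" and is reported separately as `max_raw_sd`). A cell with
identically zero SD gets an all-zero normalized image and a degenerate
flag — never NaN.

**Radial profiles.** Rays are cast from the nucleus-mask centroid every θ
degrees (θ must divide 360; θ = 10° → 36 candidate lines, θ = 1° → 360).
If the centroid falls outside a non-convex nucleus mask, the most interior
point (distance-transform argmax) is used and flagged. Each profile's
origin (distance 0) is the ray's **last** crossing of the nucleus boundary,
so motility is measured from the nucleus periphery outward even though rays
start at the centroid. Values are sampled by bilinear interpolation every
`sample_step_um` (default: one pixel) out to the cytosolic fraction length
(default 7 µm). Rays whose nucleus-boundary→cell-boundary span is shorter
than the fraction are **excluded**, not truncated, keeping every retained
profile the same length and the distance bins balanced; a `truncate` mode
exists for sensitivity analysis. Boundary crossings are located by marching
along the ray at 0.25 px steps against the rasterized masks. Binned
profiles use 0.5 µm bins; the overall score is the mean over all samples of
all retained lines. A cell retaining zero lines is an error ("cell too
small for the 7 µm fraction"), not a silent NaN.

**Nucleus segmentation and classification.** `gfp` mode thresholds the
temporal-mean nuclear-marker channel within the cell (Otsu, or a manual
threshold), keeps the largest connected component and fills holes. An Otsu
split is only accepted if the bright class exceeds the dark class by at
least 5 dark-class SDs; otherwise the channel carries no marker and the
error "nucleus not found" is raised — without this, Otsu happily splits
pure read noise. `mito_inverse` mode takes the largest below-Otsu dark
component of the mitochondrial channel, an inference for marker-negative
cells. A nucleus hugging the cell border on more than half of its perimeter
is flagged implausible. Cell classification (alpha vs non-alpha) thresholds
per-cell mean nuclear intensity inside the nucleus mask, by global Otsu over
cells (requires ≥ 2 cells and a non-degenerate split) or a fixed threshold.
`analyze_movie` falls back from `gfp` segmentation to the annotated nucleus
polygon, then to `mito_inverse`.

## TEM morphometry

Length and width are the major/minor full axes of the ellipse matching the
polygon's second central area moments (4·√eigenvalue of the area-normalized
covariance, the standard "fit ellipse" convention; for a rectangle this
reproduces the side ratio exactly). Area is the shoelace integral,
perimeter the vertex-chain length, and FF and circularity are computed from
the same area/perimeter pair so FF × circularity ≡ 1 to machine precision.
A minimum-area bounding-box axis definition is a documented possible
alternative; the moment ellipse was chosen as the common imaging default.

Distances are shapely boundary-to-boundary Euclidean minima, 0 for touching
or overlapping polygons, scaled to µm. A multi-component Golgi takes the
minimum over components; a cell with no annotated Golgi yields an *absent*
value (NaN column), which downstream summaries must not conflate with 0.
Mitochondrial density is Σ mitochondrial area / cell area; overlapping
mitochondrion annotations trigger a warning and the union area is used.
Mitochondrion area in a 2-D section is reported as-is (no stereological
correction). Distance to the plasma membrane is available
(`distance_to_membrane`) but deliberately not part of the headline table:
in a single 2-D section it does not bound the true 3-D proximity, so it is
labelled with that caveat.

## Ratiometric analysis

The ratio R = I476/I405 is computed only where the denominator is at least
`denom_floor` (default: 1% of the denominator channel's 99th percentile),
masking divide-by-noise pixels instead of producing infinities. The
sub-plasma-membrane shell is the set of in-cell pixels whose
distance-transform depth is ≤ 4 µm (configurable); if the shell covers the
whole cell a warning is raised. Per-frame shell means ignore invalid
pixels; frames with < 10% valid shell pixels are flagged and reported NaN.

Microdomain detection — connected shell components with R > shell mean +
z·SD (z = 2) and area ≥ 0.5 µm² — is an explicit operationalization of a
call that is made by eye in practice; both parameters are configurable and
no claim is made that they reproduce any particular observer. With the
piecewise-constant synthetic ratio fields the criterion is exact whenever
planted domains occupy < 20% of the shell, which the generator guarantees.

Rolling-ball background subtraction uses the morphological rolling-ball
estimate; for radii much larger than ~32 px the ball is rolled on a
proportionally downscaled grid and the background bilinearly upsampled
(the standard large-radius strategy). The background is clipped to lie
under the image, so corrected = image − background is always in
[0, image]. Knockdown efficiency is the background-corrected infected-group
mean as a percentage of the control-group mean; KD% = 100 − remaining%.

## Statistics

Outlier removal is a single pass: values outside mean ± 2 × sample SD, both
computed on the full input, are dropped. The rule is **not** idempotent —
re-applying it to the kept values can remove more — and this is tested as
the documented contract, not "fixed". Group summaries report mean ± SEM
(SD/√n after filtering). Inference beyond a Welch two-sample summary
(used only in synthetic parameter-recovery checks) is out of scope.

## Synthetic data: what it emulates, and what it does not

`simulate_movie` renders cells as disks (96-gon polygons) on a grid, each
with a slightly offset nucleus disk, containing anisotropic Gaussian blobs
(σ_major = length/4, σ_minor = width/4, fixed random orientation). Motile
blobs take isotropic Gaussian steps (per-axis SD `step_sigma_um` per frame)
reflected radially at the nucleus and membrane walls; stationary blobs
never move, and trajectories provably stay inside the cell polygon. The
nuclear channel is a uniform bright disk in alpha cells only. Noise is
Poisson on the signal followed by additive Gaussian read noise; bleaching
is a per-frame geometric decay applied before noise. Acquisition defaults
mirror a typical islet protocol: 18 frames at 5 s (≈ 1.5 min), ~0.2 µm
pixels.

Default photometry is a photon-rich acquisition — blob peak 3000 counts,
background 0.5, read noise SD 0.5 — with 40 blobs of 2.0 × 0.4 µm per
11 µm-radius cell, all motile. These defaults place the generator in the
regime where its stated contract holds: because per-cell max-normalization
divides by the cell's SD maximum, the zero-step condition reduces to a pure
noise-floor ratio (∝ 1/√peak-count), and only when that floor sits below
the slow-motion signal is the condition-mean motility strictly increasing
over step SD {0, 0.1, 0.3, 0.6} µm — the computational analogue of a
microtubule-depolymerization control recovering a known motility ordering.
Blob rendering uses 7σ local patches and the inter-cell pitch leaves room
for the full patch, so a noise-free movie conserves total intensity to
≲ 1e-13 relative (exact flux constancy additionally requires blob widths
resolvable on the grid, σ_minor ≳ 1.5 px, as used in the corresponding
test).

What the movies do **not** emulate: optics (no PSF beyond blob shape, no
axial drift in/out of the section), irregular cell shapes, heterogeneous
MitoTracker loading, directed (motor-driven) transport, and
membrane-potential-dependent intensity fluctuations. Passing parameter
recovery therefore shows the *pipeline* is sensitive and correctly ordered,
not that any specific biological effect size is reproduced.

`simulate_ratio_movie` builds piecewise-constant ratio fields: base ratio
inside cells, planted high-ratio disks whose centers lie within the 4 µm
shell and which revert to the base ratio at a configured frame; optional
multiplicative log-normal noise. `simulate_tem_annotations` builds
convex-ish wobbly-polygon membranes and nuclei, Golgi blobs near the
nucleus and non-overlapping elliptical mitochondria by rejection placement
(bounded retries, then a packing error). Its ground-truth distances come
from dense boundary resampling (10⁴ points per polygon, nearest-neighbour
query) — an oracle numerically independent of the shapely distance path it
validates, accurate to the sampling step.

## Problem sizes and determinism

Validation runs use deliberately small scenes: 2–4 cells per movie,
18 frames, ~300 px images; parameter recovery uses 10 seeds × 4 step
conditions and microdomain recovery 10 seeds, which is where the reported
condition means and SEM separations come from. All randomness flows from a
single `numpy.random.default_rng(seed)` per generator call; identical
configs and seeds give bit-identical arrays and byte-identical result
files (CSV float format `%.12g`, sorted JSON metadata, no timestamps).

## Known limitations

- 2-D only; the membrane-proximity caveat above is inherent to sections.
- The radial profiler assumes a star-shaped-enough cell around the nucleus
  centroid; strongly folded cells can self-occlude along rays.
- `mito_inverse` nucleus segmentation assumes the nucleus is the largest
  mitochondria-free dark region, which fails in sparse cytosol.
- The microdomain criterion is a pragmatic operationalization; its defaults
  were not fit to observer data.
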