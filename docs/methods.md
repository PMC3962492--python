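# Methods

## Image model and preprocessing

A plate photograph is treated as an RGB or grayscale raster with
intensities scaled to [0, 1] (integer images are divided by their dtype
maximum).  Grayscale conversion uses the luminosity weights 0.2/0.72/0.07
for R/G/B; already-gray images pass through unweighted.  The pipeline
assumes colonies are brighter than the background — dark-colony images
must be inverted (`invert` option), which is the user's call because the
pipeline cannot know the imaging polarity.

Stage order is grayscale → fast resize → inversion → contrast →
autorotation → background subtraction.  Rotation estimation benefits from
inversion/contrast having been applied, and background subtraction runs
last so that the zero-filled corners introduced by rotation are not
treated as background structure.  Contrast adjustment, when requested, is
linear about the global mean (`mean + f·(x − mean)`, clamped), the
simplest monotone definition with factor 1 as identity.

**Rotation.**  Candidate tilts are searched on a ±30° lattice with 0.2°
steps — plates are physically registered before photography, so real
tilts are a few degrees, and the bound comfortably covers them.  The
image is downscaled to 500 px wide and the Radon transform R(r, α)
evaluated at 90° + α; the tilt is the α maximizing the variance of R over
offsets r.  The Radon transform (`skimage.transform.radon`,
`circle=False`) is used rather than literally rotating and row-summing:
its uniform diagonal zero-padding treats every candidate angle
identically, whereas rotating the raw bright-background image introduces
corner-fill zeros whose row-sum variance contribution grows with |α| and
biases the argmax.  The two formulations integrate the same family of
lines.  Correction rotates by the negative estimate with bilinear
interpolation and zero fill; the 0.2° lattice bounds the residual tilt at
0.1°, well under the 0.3° recovery tolerance the tests assert.

**Background.**  The background estimate is the grayscale opening with a
w×w square structuring element, w = 1.5 × image width / colony columns,
rounded to odd.  A window wider than a colony guarantees erosion collapses
colonies into the local background; subtracting the opening leaves
colonies on a near-zero background.  Negative residuals are clamped to 0
so every stage maps [0, 1] to [0, 1].

## Thresholding

The two-class mean-split (intermeans) iteration: t starts at the global
mean; cluster means are the averages of pixels < t and ≥ t; t moves to
their midpoint.  Convergence is declared at |Δt| < 1e−7 with a 100-round
cap against floating-point cycling, and the iteration stops early if a
cluster would empty.  Pixels exactly at t are foreground, consistent with
the mask rule `I ≥ t`.  Optional speckle removal is a plain 3×3 binary
erosion — the smallest kernel that deletes single-pixel noise; it also
shaves a one-pixel rim off every colony, which is accepted and documented
rather than compensated (an opening would restore the rim but also
reconnect noise).

## Grid fitting

Projection profiles T_i (foreground counts per row/column) are the grid
signal.  The colony half-width W is half the median distance between
local maxima of the smoothed profile (moving average, window 5),
restricted to the middle 50% of the axis so plate edges cannot
contaminate the estimate.  Two robustness details: maxima closer together
than the smoothing window are merged (rasterized flat-topped colony peaks
can split into twin maxima two pixels apart, which would collapse the
median gap), and a maximum must have prominence of at least 10% of the
profile's dynamic range (colony peaks are hundreds of counts tall, while
speckle and noise bumps are a few counts and would otherwise flood the
median).  Note that by construction W is half the colony *pitch*; on real
plates colonies nearly fill the pitch so this doubles as the colony
radius, and the correlation step only needs the template shape, not an
exact radius.

The chord template λ_w = 2√(W² − w²) (the vertical chord of a circle of
radius W) is slid along the profile; r_i is the Pearson correlation
between template and the window centered at i.  Windows that extend past
the profile ends or have zero variance get r = 0 rather than a partial
correlation, avoiding spurious edge peaks.  Candidate centers are strict
local maxima with r > 0.3.

The n true peaks are chosen by the likelihood
`L(s) = Π N(x_{k+1} − x_k; μ_δ, σ²_δ) · Π N(r_{x_k}; μ_r, σ²_r)` over the
n-length consecutive runs, computed in log space; μ_δ is the plain mean
of the N−1 candidate gaps and the variances are population variances over
all candidates, floored at 1e−6 because perfectly regular synthetic grids
have zero gap variance.  Ties take the smallest start index.  Rows and
columns are fitted independently; δ is the median gap pooled over both
axes (one plate, one pitch), and the stored W is the rounded mean of the
two per-axis estimates.

Plate-density tokens map to 96 → 8×12, 384 → 16×24, 1536 → 32×48,
6144 → 64×96, the standard microplate geometries.

## Colony measurement

Within a search square of side round(1.5 δ) about the grid center, the
bounding rectangle sides sit at the local minima (plateau-tolerant,
value ≤ both neighbors) of the cropped mask's marginal foreground-count
profiles — the nearest minimum to the center on each side that is at
least round(δ/3) away; a side with no qualifying minimum falls back to
the search-square edge.  The marginal profiles are computed on the
thresholded mask, not grayscale: the grid was fitted on the mask, and
counts are robust to residual lighting.  If the center pixel is
background the colony is deemed absent and a default δ-wide square is
recorded instead.

Area A counts foreground pixels inside the (inclusive) rectangle.  P
counts foreground pixels with a 4-neighbor that is background, where
pixels outside the rectangle count as background so P is well defined at
crop edges.  Circularity is 4πA/P², reported as computed even in odd
cases (a single-pixel colony scores 4π; rasterized disks score slightly
above 1 because the discrete boundary count underestimates the continuous
perimeter).  Flags: `overlap` when the rectangle's one-pixel perimeter
ring contains any foreground (no clean separation from a neighbor);
`lowcirc` when 0 < circularity < 0.6.  Plate-level flags fire when at
least 10% of all grid positions (empty cells included) are smaller than
0.1× the median size, or have circularity below 0.6.

## Sparse plates and batch

A reference image is preprocessed, thresholded, and gridded normally; its
layout, δ, W, and projection profiles are retained.  A target image of
identical dimensions is aligned per axis by the integer shift k
(|k| ≤ δ/2, beyond which the alignment would alias onto the neighboring
grid line) maximizing the Pearson correlation of the overlapping profile
regions, ties broken by smaller |k| then smaller k; sub-pixel alignment
is not attempted because quantification operates on integer crops.  A
best correlation below 0.2 logs a warning.  Batch processing isolates
per-image failures (logged, `None` in the result slot) and preserves
input order; only an unreadable reference is fatal.

## Synthetic plates

The generator renders rasterized disks (or unions of 2–3 offset disks for
irregular morphology) at known centers, then layers artifacts in a fixed
order — gradient, crack, plate edges, speckles, Gaussian noise,
inversion, translation, rotation — so the ground-truth geometry transform
is one integer shift plus one rigid rotation applied last.  Default
conditions: colonies at intensity 0.9 on 0.1 background, radius one
quarter of the pitch, and a margin of two pitches between the outermost
colony centers and the image border with the bright agar rim (when
rendered) at least one pitch clear of the outer colonies — matching how
arrayed plates are photographed, where the dish rim never touches the
colony array.  Per-cell random draws are stream-aligned so a dense and a
sparse plate generated from the same seed share colony radii, giving
sparse-reference tests an exact per-colony truth.

What the generator does not emulate: agar texture, lens distortion,
specular highlights, colony halos, and gradual colony edges (rendered
colonies are binary-sharp).  Passing tests therefore demonstrate the
geometry and measurement logic — grid recovery, boundary fitting, exact
pixel accounting — not photometric robustness to camera effects beyond
the modeled gradient/noise/speckle classes.

## Problem sizes and determinism

Tests run on 96/384/1536-format synthetic plates (images up to
~560×816 px), 20-plate recovery sweeps, 27 rotation estimates, and
200-instance oracle comparisons; these sizes exercise every code path at
full plate density while keeping the suite quick.  All randomness lives
in the generator and test seeds; the pipeline itself is deterministic, so
identical inputs give bit-identical outputs, including the `.dat` files.

## Known limitations

Only rectangular grids with uniform pitch are supported; no hexagonal or
per-row-variable layouts.  Rotation correction assumes |tilt| ≤ 30°.
Very small formats cannot be gridded independently: half-width estimation
needs at least three colony peaks in the central half of each axis, so
plates with fewer than ~3 rows or columns require a reference.  The
low-circularity constant 0.6 is reused as the per-colony flag threshold
because no separate per-colony value is defined.  Heatmap/bubble
visualizations of colony sizes are out of scope; the gridded overlay is
the supported diagnostic.
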