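# Methods

## Scope and design stance

The package quantifies segmentation quality for CTC enumeration in
CellSearch-style cartridges. Clinical image archives are proprietary, so
every stage is exercised against a ground-truthed synthetic cartridge
simulator; the audit statistics themselves (recovery, quality classes,
size audit, density CDFs, regressions, edge heatmap) are defined
independently of where the label maps come from, and external label maps
can be substituted for the built-in segmenter.

The segmentation stage is deliberately classical and training-free. The
quantity under study is the *pipeline around* a star-convex segmenter —
gating, matching, auditing — not network training; a deterministic
probability proxy keeps the artifact fully reproducible on one CPU, and
the stage is pluggable for anyone who wants to drop in a learned model's
label maps.

## Synthetic cartridge model

A cartridge is `n_frames` (default 140) frames of 977 × 1211 px at
0.64 µm/px, 12-bit counts. The defaults encode the instrument's
conventions: 0.64 µm/px makes a 32 × 32 µm² square exactly 2500 px (the
canonical single-large-cell segmentation size) and lets a 25 × 31 grid of
~25 µm bins tile a frame; 12-bit depth is assumed, chosen so the
candidate-gate thresholds (tens to hundreds of counts) sit plausibly
within range — the true instrument bit depth is not documented.

Object classes and their fluorescence signatures:

| class | DAPI | CK-PE | CD45-APC | radius (px) |
|---|---|---|---|---|
| tumor cell | + (nucleus only) | + | − | 7–10 |
| leukocyte | + | − | + | 5–7 |
| tdEV | − | + | − | 1.5–3 |
| bare nucleus | + | − | − | 4–6 |

Per-class, per-channel intensities are log-normal. No public source gives
these distributions; the medians are anchored so the candidate-CTC gate is
meaningful — tumor PE and nucleated DAPI medians at 300 counts, leukocyte
APC at 300, tdEV PE at 200, background at 20 — i.e. an order of magnitude
above the gate's mean thresholds (45–50), with σ = 0.35–0.45 giving a
realistic spread including occasional faint (~100-count) and bright
(~1500-count) objects. This calibration was fixed once, before any
downstream evaluation, and is configurable.

Shapes are star-convex blobs: 32 radii modulated by smoothed circular
Gaussian noise (±18%), rasterized and filled. Tumor cells render a
concentric nucleus blob at 0.65× the cell radius so DAPI is interior to
PE. With probability `nonstarconvex_fraction` (default 0.05) a tumor cell
is a dumbbell of two fused lobes — a shape one star-convex polygon cannot
represent, emulating the known failure class. With probability
`clump_fraction` (default 0.1) an object center is drawn at 0.9–1.2× the
sum of radii from an existing object, producing touching pairs that defeat
contour-joining segmenters. Other centers are uniform, rejecting centers
that land inside an existing object (touching and partial overlap still
occur, as in real dense samples). Requested densities whose expected
coverage exceeds 90% of the frame raise an explicit placement error.

Signal model per frame: object signal × vignetting + background, then
noise. Vignetting is quadratic in distance from the frame center, reaching
`1 − vignetting_strength` (default 0.7) at the corners — this is what
makes edge events systematically fainter. The APC channel receives
`pe_to_apc_crosstalk` (default 0.05) times the PE signal, mirroring real
PE→APC spectral bleed; the gate's "PE mean > 1000" override exists
precisely because of this effect. Noise is Gaussian with
σ = `noise_sd` + `poisson_scale`·√signal (defaults 4 + 0.5√s), clipped to
the bit depth and quantized to uint16.

Sample-age effects are modeled as leukocyte-count multipliers: blood
{1, 2.15, 2.85, 4.15} for 1/2/3/4+ days between collection and
preparation (ratios of the observed per-day median event counts
13/28/37/54 thousand), DLA {1, 1.26, 1.28, 1.44} (from 108/136/138/156
thousand). This is a calibration to observed medians, not a mechanistic
model of non-specific binding.

Randomness: one root seed; frame assignment comes from the root stream and
each frame's placement/rendering from a counter-derived child stream
(`SeedSequence(seed, spawn_key=(frame,))`), so results never depend on
evaluation order and reruns are bit-identical.

### What the simulator does *not* emulate

No optical PSF, no autofocus failure, no cartridge plastic-edge
autofluorescence, no broken/apoptotic cell debris, no CTC clusters as a
distinct class, and intensity distributions are assumed log-normal rather
than measured. Passing tests therefore demonstrate correctness of the
pipeline's logic and its behavior under controlled density/contrast/noise
regimes — not calibrated performance on instrument data.

## Star-convex geometry

A polygon is a center plus K ray distances at angles 2πk/K; K defaults
to 32 (a common choice balancing angular resolution against cost) and is
configurable. Mask→rays uses ray marching at 0.25 px steps (radial
quantization below rasterization error), recording the last in-mask
sample. Rays→mask rasterizes the K-gon with 3× supersampling, keeping
pixels where at least half the subsamples are inside: a plain
boundary-inclusive scanline fill overestimates area by ~half the perimeter
in pixels, which is material for 100–300 px cells and for the event-area
gate. Round-trip fidelity (mask → rays → mask) exceeds 0.90 IoU on random
star-convex blobs at K = 32.

Overlap is rasterized IoU on the pixel grid (restricted to the joint
bounding window), not analytic polygon clipping — masks are what the
downstream feature extraction consumes, so the IoU used for suppression
matches the IoU of the objects actually produced. Whether the original
post-processing suppressed on IoU or intersection-over-smaller is not
documented; IoU was chosen. NMS is greedy: descending score, ties broken
by input index for reproducibility; a candidate is kept iff IoU with every
kept candidate is ≤ `nms_thresh` (default 0.3).

## Segmentation stage

1. **Local contrast enhancement**: sliding-window min–max normalization
   (window 65 px ≈ 42 µm — larger than a cell, smaller than a clump; the
   known trade-off is that smaller windows rescue faint-near-bright events
   but break up densely packed regions). Two guards are added: windows
   whose dynamic range is below `min_contrast` (60 counts) map to 0, so
   read noise is not stretched to full scale; and the normalization
   denominator is capped at `enhance_max_range` (400 counts), so one very
   bright cell cannot crush a faint neighbor in the same window below the
   foreground threshold. Both default to off (0 / ∞) in the standalone
   `local_contrast_enhance` function, which then computes the pure affine-
   invariant min–max map.
2. **Foreground**: max of enhanced DAPI and enhanced PE > 0.25. Using the
   channel maximum admits single-channel events (tdEVs, bare nuclei).
3. **Object probability**: the smoothed enhanced image multiplied by the
   interior distance transform normalized by its local maximum over
   ~one cell diameter (13 px). Local rather than per-component
   normalization matters at high density, where many cells share one
   foreground component and a component-wide maximum would suppress all
   but the largest. Peaks above `prob_thresh` (0.3), with a 3 px minimum
   separation, are candidate centers.
4. **Candidates**: each peak's support is delimited by marker-controlled
   watershed of the foreground distance transform (markers = peaks), then
   ray-cast into a star polygon; the score is the peak probability.
   Watershed delimitation is what resolves touching cells into separate
   polygons — ray-casting the raw connected foreground would give every
   peak in a clump the whole clump's outline.
5. **NMS** at 0.3, then rasterization into a label map in descending score
   order (higher score wins contested pixels); each label is reduced to
   its largest 4-connected piece, labels are contiguous 1..n, and the
   whole stage is deterministic.

## Event features and the candidate-CTC gate

Features are computed on the **raw** channels (the gate thresholds refer
to instrument intensities, and enhancement is non-linear). The gate:
PE max > 75 ∧ PE mean > 45 ∧ DAPI max > 60 ∧ DAPI mean > 50 ∧
(APC mean < 50 ∨ PE mean > 1000) ∧ 36 ≤ area ≤ 1000 px ∧ stained-PE
area ≥ 30 px. Intensity clauses are strict (the definitions use ">"/"<");
area bounds are read inclusively ("between 36 and 1000") with a
configurable strict mode. "Stained" is not defined anywhere; the PE stain
threshold defaults to 45 (the same scale as the PE-mean clause) and is
echoed into output metadata. Failed clauses are reported by name so
gate decisions are auditable. Novel candidates are gate-passing events
whose centroid falls inside no reference rectangle (the instrument's
10 px-margin bounding boxes around DAPI+/PE+ events).

## Matching and audit statistics

Quality classes per reference object: *missed* if no test label overlaps
≥ τ_min = 0.2 of its mask; *merged* if its best-matching label also
overlaps ≥ τ_min of another reference; *split* if ≥ 2 labels each overlap
≥ τ_min; *partial* if matched labels cover < τ_cov = 0.8 of it; else
*correct*. The published review used human judgment with no numeric rule;
τ_min/τ_cov were chosen to reproduce the intuitive semantics and are
exposed in the API. Recovery = 100·(n − missed)/n, reported at 2 decimals
with quality rates at 1 decimal (the conventional precision); unrounded
values are kept alongside for downstream arithmetic.

Size audit bins: ≤2500 px (regular), 2500–25,000 (larger than a cell),
25,000–100,000 (too large to review), >100,000 (very large), intervals
half-open (low, high]. Per bin: % of samples containing one, mean/range %
of cartridge area, mean/range % of segmented area (summing to 100 across
bins per sample set).

Density CDFs are right-continuous empirical CDFs per days-to-prep group;
first-order stochastic dominance of A over B requires CDF_A ≥ CDF_B on
the pooled support with strict inequality somewhere (antisymmetric by
construction).

Regressions (spike-in correlation; CTC gain) are ordinary least squares
with intercept via statsmodels; R² is the standard centered 1 − SS_res/SS_tot.
The gain analysis enforces combined ≥ original (review can only add CTC)
and tallies <5 → ≥5 risk-group conversions and zero → nonzero gains.

Edge heatmap: 25 × 31 equal-size bins tiling the frame exactly (25 along
height, 31 along width, matching the frame aspect); edge bins are the
grid's perimeter. The uniform expectation is area-weighted — edge-bin area
over frame area, 108/775 ≈ 13.9% for equal bins. A published figure
quotes 14.5% for the uniform expectation of the same grid without stating
its rule; the discrepancy with the perimeter-count fraction is documented
here and the package reports its own area-weighted value.

## Numerical and degenerate-input choices

- Rasterization is pixel-grid based throughout; empty rasterizations give
  IoU 0 by definition.
- Ray distances have a floor of one marching step (0.25 px) so polygons
  always have positive area.
- `recovery_report` refuses empty reference sets; `density_cdf` drops
  empty groups with a warning; `size_audit` excludes segmentation-free
  samples from segmented-area means.
- Label maps are written as 16-bit TIFF; >65,535 labels per frame is an
  error.
- All percentages are emitted both unrounded and at reporting precision.

## Problem sizes for the seeded checks

The test suite and `scripts/acceptance.py` run the simulator at desk
scale: sparse recall uses 500 isolated cells over eight 256 × 320 px
frames; dense recall uses 256 × 336 px frames at the same per-area density
as ~3000 objects on a full-size frame (~218 objects/frame, ~27% coverage —
the maximum density the instrument can autofocus); the touching-cell check
uses ten seeded two-cell frames. These sizes were chosen as the smallest
configurations that still exercise the density regimes of interest.
Engineering targets on these synthetic conditions: ≥ 95% recall isolated,
≥ 85% recall dense, touching pairs resolved as two events (never one);
occasional oversegmentation of an irregular cell into three events is
tolerated, mirroring the ~1% split rate seen in real reviews.

## Known limitations

- The probability proxy is not a learned model; its absolute recall on
  instrument data is unknown. The audit statistics, not the segmenter,
  are the transferable part.
- Gate thresholds assume the simulator's intensity calibration; absolute
  comparability to instrument counts is unverifiable without archives.
- Overlapping ground-truth objects (unavoidable at high density) make the
  merged class partly a property of the simulation, not the segmenter.
- Dumbbell (non-star-convex) tumor cells are emulated, but the other
  documented failure modes (faint-near-bright false negatives at the
  plastic cartridge edge) are only partially represented via vignetting.
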