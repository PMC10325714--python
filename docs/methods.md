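# Methods

## The deformation coefficient

Each gland is reduced to three polyline arc lengths and a width profile.
In the gland's own frame (axis vertical), the left and right boundaries
have arc lengths `pa` and `pb`; the central line — the straight segment
joining the first and last midpoints, i.e. the *string* of the arc-string
tortuosity model — has length `L_central`. Widths `w_i` are sampled once
per step (default 1 px) along the axis; their mean is `w_avg` and their
variation term is

```
sigma_w = sqrt( sum_i (w_i - w_avg)^2 / (n + 1) )
```

with `n` the number of samples. The `n + 1` denominator is retained as
published; a config switch (`sigma_denominator`) offers `n` and `n - 1`.

Three combiners are implemented:

| variant | formula | units | minimum (straight uniform gland) |
|---|---|---|---|
| `as_printed` | `(pa·pb/L²)·sigma_w` | px | 0 |
| `normalized` | `(pa·pb/L²)·(sigma_w/w_avg)` | — | 0 |
| `normalized_plus_one` (default) | `(pa·pb/L²)·(1 + sigma_w/w_avg)` | — | 1 |

The published formula is the first row, yet the score is described as
dimensionless with minimum 1 — properties that literal reading cannot
satisfy (its width term carries pixels and vanishes on a uniform gland).
The default variant divides the width spread by the mean width and adds
the identity, which preserves both stated properties while reducing to
the pure arc-chord ratio when the width is constant. All variants remain
selectable and are recorded in every output row.

A note on `L_central`: treating the central line as the *curved* midline
would make `pa·pb/L²` ≈ 1 for every gland (boundaries of a tube are
nearly parallel to its midline), so the score could never separate
straight from sinuous glands. The chord reading is the only one under
which the arc-chord factor measures tortuosity, attains 1 on a straight
gland, and reaches the 6–8 range observed at the most deformed central
positions.

## Geometry extraction from masks

Components are 8-connected, ordered left-to-right by centroid column
(ties by topmost row), and components under `min_area` (64 px) or touching
the image border are discarded. For one component:

1. **Frame.** Pixel coordinates (never the raster) are rotated into the
   gland frame. A second-moment (principal-axis) estimate supplies the
   coarse orientation, used only when the component is closer to
   horizontal than vertical; the frame is then refined (≤3 iterations) so
   that the central chord is vertical. The refinement matters because the
   raw second moments of a sinuous gland are biased by its lateral
   excursions — up to ~10° of spurious tilt for a single-period sinusoid.
2. **Profile.** Rows of `step_px` (default 1) bin the coordinates; per
   row the leftmost/rightmost positions give the boundary samples, the
   width `w_i = right − left + 1`, and the midpoint. An empty interior
   row raises `fragmented gland`; fewer than 2 rows raises `gland too
   short`.
3. **Smoothing.** Raw pixel-quantised boundaries form a staircase whose
   polyline length is biased upward (≈ +8% at slope 0.5), so boundary
   sequences are smoothed with a quadratic Savitzky–Golay filter before
   arc lengths are measured. The window adapts to the measured boundary
   slope (11 rows at shallow slopes down to 5 at steep ones): at steep
   slopes quantisation noise is negligible relative to the per-row
   excursion while wide windows clip curvature extrema. Widths get a
   3-row moving average against the same jitter. On cohort-scale glands
   this keeps extracted `D` within ~0.04 of the analytic value across the
   full range generated (up to `D ≈ 13`), and axis-aligned rectangles are
   measured exactly (`D = 1.0`, no approximation).

Sampling is along the fixed gland axis rather than along local centerline
normals; for the near-vertical glands of upper-eyelid meibography the two
coincide to within the smoothing scale, and the fixed axis is reproducible
on noisy masks.

## Central-region selection

The midline is the area-weighted centroid column of all gland pixels
(robust to a stray peripheral gland; the midpoint-of-extremes alternative
is deliberately not the default). Five glands nearest the midline are
selected per side; a centroid exactly on the midline joins the side with
fewer glands, ties to the temporal side. Numbering runs 1 (most temporal)
to 10 (most nasal). For en-face views the temporal side defaults to image
left for OD and image right for OS, and is always overridable because
device mirroring conventions vary.

## Synthetic glands and scenes

A gland is parameterized by length, base width, sinusoid amplitude /
wavelength / phase for the centerline, and a linear width taper. A pixel
is foreground when its column lies within half the local width of the
centerline column of its row ("horizontal offset"). This convention keeps
the two ingredients of `D` independently controllable — amplitude drives
only the boundary arc lengths, taper drives only the width variance — and
makes the analytic ground truth (dense trapezoid integration of the
boundary curves, widths sampled per row) exactly the quantity the raster
extractor estimates. A perpendicular-tube rasterization was rejected
because its per-row silhouette widths inflate with centerline slope,
coupling the two terms and making a constant-width sinuous gland appear
width-irregular.

Scenes place non-overlapping glands on an even pitch and render 8-bit
images as smoothed mask intensity (foreground 200, background 20,
Gaussian blur σ=1.2) plus additive Gaussian noise, clipped to [0, 255].
Scene generation is a pure function of its seed.

## Paired cohorts

The generator emulates a paired ocular design: per subject, a treated eye
and the untreated contralateral eye (laterality assigned at random), each
carrying 12 glands — the 10 indexed central glands plus one baseline
flanker per side so central-region selection has margin. Per gland `g`:

```
control target   = baseline_g + u_sg + e_sg
treatment target = baseline_g + effect_g + u_sg + e'_sg
```

`u` is subject-level noise shared by both eyes (variance `ρ·sd_g²`),
`e` eye-level noise (variance `(1−ρ)·sd_g²`). Defaults are the study
conditions the pipeline is built around: 36 subjects; `baseline_g` from
the control-group site profile (means 1.62–2.49); `effect_g` from the
paired-difference profile (0.077–4.96, largest at the central positions
5–6); `ρ = 0.5`; and `sd_g` equal to the published per-gland
paired-difference SDs, so that `sd(diff) = sqrt(2(1−ρ))·sd_g` reproduces
that profile exactly (e.g. 3.536 for gland 5). `noise_sd` accepts a
scalar or a 10-vector.

Targets below a gland's geometric floor — its `D` at zero amplitude,
1.03–1.15 depending on taper — are truncated to the floor: a Gaussian
additive model necessarily produces sub-floor draws, and i.i.d.
truncation of both eyes preserves the symmetric null of the paired test
(type-I calibration is verified empirically at 0.05 ± 0.02). The
truncation censors the control tail when noise is large relative to the
baseline-floor gap, which is why parameter recovery of the mean effects
is verified in a low-noise configuration; under the full published noise
profile the realized gland-5 mean difference is smaller than the nominal
4.563 but the paired test still rejects in ≥99% of cohorts
(noncentrality ≈ 7.7).

Amplitudes are solved from targets by inverting `D(amplitude)`, which is
strictly increasing. Cohort glands span exactly three sinusoid periods
(361 rows, wavelength 120 px), making the boundary arc integrals
phase-invariant; this allows a single phase-averaged amplitude↔D table
per taper magnitude (trapezoid on a 2049-point period grid, interpolated
inversion), so thousand-cohort Monte-Carlo runs stay inexpensive while
`solve_amplitude_for_d` (Brent on the dense analytic geometry) provides
the exact per-gland route. Realized and analytic `D` agree to ~2×10⁻³.

Pixel scale is arbitrary: no acquisition geometry is assumed, justified by
the scale invariance of `D` (verified to <2% across 1×/2×/3× rasters).

## Augmentation policy

Eleven registered transforms: crop, horizontal flip, cutout, x/y
translation, rotation, x-shear (geometric — identical parameters for
image and mask, mask by nearest neighbour) and histogram equalization,
contrast, brightness, sharpness (photometric — image only). A policy
draws N (default 2) distinct transforms and per-op magnitudes M ∈ 1..10;
each transform maps M linearly onto its documented range (rotation
±3°·M, translation 3%·M, shear 0.03·M, crop margin 2%·M per side, cutout
side 4%·M, equalize blend 0.1·M, contrast/brightness factor 1±0.08·M,
sharpness 1+0.19·M). Magnitudes are sampled per-op (whether the original
scheme sampled per-op or per-policy is unstated; per-op is the superset).
Out-of-canvas pixels are filled with 0 / background; output dimensions
are always preserved.

## Segmentation baseline

`segment_baseline` is a deliberate classical stand-in behind the stage
contract (`image -> binary mask`), so a learned segmenter can be dropped
in without touching downstream code: background subtraction (Gaussian,
σ=25 px), local adaptive threshold (Gaussian-weighted, 75-px block,
offset 25 counts), opening (disk radius 1), and removal of components
under 64 px. Defaults were tuned once on generator scenes and reach
IoU ≥ 0.9 against ground truth on noise-free renders. Empty-denominator
conventions for the metrics: sensitivity is 1 when truth has no
foreground, specificity 1 when truth has no background, IoU 1 when both
masks are empty. Aggregation over images defaults to the mean of
per-image IoU; pooled-confusion aggregation is available.

## Statistics

Paired t per gland on treatment−control differences (two-sided, df = n−1,
CI = mean ± t₀.₉₇₅·SE); one-way ANOVA across the ten gland positions per
group (from raw values, or from means/SDs via `MSB = n·Σ(mᵢ−m̄)²/(k−1)`,
`MSW = mean(sᵢ²)`); Fisher LSD pairwise comparisons on the pooled MSW.
The compressed LSD string orders group means descending and greedily
builds blocks: a group joins the current block if non-significant against
every member, starts a new block if significant against every member, and
is otherwise listed as unplaced; a single all-inclusive block yields an
empty string. No multiple-testing correction is applied across the ten
paired tests by default (matching the reference analysis); a
Benjamini–Hochberg column is available via `fdr_correct=True`.

Summary-row reconstruction uses the identities `t = mean/SE`,
`CI = mean ± t·SE`, `n = (SD/SE)²`. For the bundled reference rows these
recover n = 36 per group uniformly — note the study's headline count of
68 eyes per group is not consistent with its own printed SD/SE ratios, so
the reconstruction utilities take n explicitly rather than assuming the
headline. Printed t and F values reproduce to within the rounding of
their 3-decimal inputs (≤0.5% relative). Two published quantities are
*not* reconstructible from their printed summaries (a paired t of 45.445
without the SD of differences, and an independent t of −11.393 whose
summaries imply −12.29); these are flagged in tests, not asserted.

## Known limitations

- The synthetic gland family (sinusoidal centerline, linear taper) spans
  straight-to-distorted but not branching, fragmentation, dropout or
  atrophy; passing tests demonstrate correctness of the measurement
  pipeline, not realism of infrared texture or pathology.
- Width sampling along the fixed axis underestimates local width on
  strongly bent glands relative to normal-section sampling.
- Glands whose central chord is strongly tilted within the image are
  measured in their own chord-aligned frame; the synthetic ground truth
  assumes a near-vertical chord, as in upper-eyelid meibography.
- The classical segmentation baseline is tuned to the generator's
  contrast model and is not expected to transfer to clinical imagery;
  it exists to exercise the pipeline contract.
- Cohort noise is independent across glands within an eye (only the
  within-subject between-eye correlation is modelled).
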