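# Methods

This note documents the measurement conventions, the synthetic-data model,
the numerical choices, and the limits of what the test suite demonstrates.

## Coordinate and angle conventions

Pixel coordinates are 0-based pixel-centre `(x, y)` with y increasing
downward. Azimuths are `degrees(atan2(dy, dx))` in those coordinates, so
increasing azimuth is clockwise on screen. All angles are degrees, all
physical lengths µm; outputs carry `_deg` / `_um` / `_pct` suffixes.
Defaults mirror the acquisition setup the pipeline is built around:
0.1 µm/px in-plane, 0.6 µm z-increments for live stacks, 0.3 µm for
fixed-cell stacks, 2.5–3 min frame intervals.

## Cortical profiling

`fit_ellipse` is a direct least-squares conic fit with ellipse constraint
(scikit-image's `EllipseModel`): deterministic, no initialisation, exact on
noise-free elliptical contours. The fitted ellipse anchors the angular
coordinate system; the residual RMS is reported so poor contours are
visible.

`scan_cortex` reports, for each of 180 positions 2° apart, the maximum
bilinearly interpolated intensity along a 30-px segment sampled at 1-px
steps, **centred on** the ellipse boundary and directed along the local
outward normal. Centring is a committed choice — the macro convention this
reimplements only requires the segment to overlap the cortex; centring makes
the capture window symmetric (±15 px) and is what the probe-pixel test
verifies. Position 0 faces the reference axis: the metaphase-plate axis for
metaphase cells, the ellipse short axis for the prometaphase variant (where
the plate is assumed to align with the cell's elongation); the scan proceeds
in the direction of increasing image azimuth. 180 unique positions are
emitted (the wrap-around sample at 360° would duplicate position 0).

Background correction subtracts a single scalar per image — the median of a
user-supplied, cell-free ROI — and floors at 0; the subtracted value is
recorded on the profile. Average profiles are position-wise mean ± s.e.m.
(sample sd / √n, n ≥ 2 required).

### Localisation classifier

The five categories are operationalised from summary statistics of the
background-corrected profile: lateral mean `L` (±30° around 90° and 270°),
central mean `C` (±30° around 0° and 180°), coefficient of variation `U`,
and a robust peak level (90th percentile). Decision order: *absent* when the
peak level does not exceed `absent_threshold` (2×) times the noise floor;
*circumferential* when `U < 0.15`; *central* when `C > 1.3 L`; *bilateral*
when both lateral lobes exceed `1.3 C` and agree within 2-fold; *unilateral*
when one lobe dominates; *circumferential* otherwise. All thresholds live in
`ClassifierConfig` — they are tunable operating points, not biological
claims.

The noise floor deserves a note: because the scan reports a **maximum** over
31 radial samples, a signal-free profile sits roughly two noise standard
deviations above the corrected background, not at zero.
`estimate_profile_noise_floor` therefore computes the same max-statistic
over groups of background-ROI pixels, and the absent rule compares the
profile's upper level (90th percentile rather than the mean, which a single
narrow crescent barely moves) against it.

## Fixed-cell metrics

Intensities are background-corrected sums, `sum(I) − area · background`,
over user-supplied masks; the module measures and never segments, matching a
manual-ROI workflow. The ratio formulas
`(I_total − I_spindle)/I_spindle` and `(I_total − I_cytoplasm)/I_cytoplasm`
are scale-invariant and non-negative for nested regions. Sums (not means)
are used; for the nested-region formulas a mean-based variant differs unless
areas cancel, so the convention is fixed and documented here. Spindle tilt
is computed from voxel-size-scaled coordinates — z-anisotropy is explicit,
never hidden in pixel indices.

## Time-lapse conventions

The in-plane trace references frame 0 (not the previous frame); the spindle
axis is undirected, so rotations wrap to (−90°, 90°], and pole-label swaps
between frames are resolved by nearest-predecessor matching. The z-trace
sign rule is a committed reading of "poles changed direction": the sign
stays positive while the same physical pole is the higher one and flips at
each identity reversal; planar frames report 0 and leave the reversal state
untouched.

Oscillation events are consecutive-frame deviations **strictly** greater
than 10°; the index divides by the total frame count (not frames − 1), read
literally from the source convention; both the threshold and the denominator
are configurable. One threshold serves both axes.

## Acinus morphometrics

Shape descriptors follow the Fiji conventions: circularity `4πA/P²` capped
at 1, roundness `4A/(π·major²)`. The major axis comes from the polygon's
exact second moments (Green's-theorem closed forms) — the moment-equivalent
ellipse — rather than a least-squares fit to the vertices, which is
undefined for polygons with fewer than five vertices. Both circularity and
roundness are emitted for lumens since either may be wanted.

The basement-membrane tangent at a mitotic site is the orientation of a
least-squares line through the outline path within ±15 px of arc length
around the boundary point nearest the spindle midpoint; the division angle
is the pole axis folded against that tangent into [0°, 90°], with the planar
bin at ≤ 30°. The mean angle mα is the arithmetic mean on [0°, 90°] (a
circular mean is unnecessary on a folded half-quadrant range). Apical
vs. basal border pixels are split by comparing Euclidean distance transforms
to the lumen set and to the outline; a "normal lumen" requires exactly one
lumen above the 5 µm² size filter plus apical/basal border-mean enrichment
above a configurable factor (default 1.5).

## Synthetic scenes: what they emulate, and what they do not

The generators reproduce the *statistical structure the analysis assumes*:
an elliptical cell with a cortical band whose angular intensity follows one
of the five patterns (Gaussian crescents in angle, FWHM 60° by default, on
the shortest angular distance; bilateral adds an antipodal copy), a DNA
plate bar defining the 0° reference, pole pairs on the spindle axis, astral
segments of known length and photon count, angle traces whose planted events
are baseline steps of alternating sign with jitter bounded strictly below
the event threshold, isotropic-step tracks, and ring acini with
apically-enriched lumen-facing membranes. Noise is additive Gaussian from a
single integer seed per call; identical seed and parameters give
bit-identical arrays.

Defaults are fixed study conditions: 512×512 px at 0.1 µm/px, cell ellipse
120×90 px, cortical band σ = 4 px (FWHM ≈ 0.9 µm — a realistic cortex
thickness that also keeps the noise-free render/scan discretisation ripple
below the 1% tolerance the flatness checks assert), peak 1000 AU over
100 AU background; SNR is expressed as (peak − background)/noise_sd.
Event traces reject magnitudes ≤ threshold + 2·jitter_bound: anything
smaller can be masked (or doubled) by jitter and the planted count would be
ambiguous — this is deliberately stricter than requiring the magnitude to
exceed the jitter alone.

Not emulated: point-spread blur and spectral bleed-through, Poisson shot
noise (an optional concern the additive model sidesteps), mitosis
progression phenotypes, irregular cell shapes, out-of-focus light, or
multi-layered acini. Passing recovery tests therefore demonstrates that the
*measurement chain* is correct and well-conditioned at realistic SNR; it
does not certify performance on real images with segmentation errors or
structured background.

## Numerical choices and degenerate inputs

Bilinear interpolation throughout (1-px steps); sampling paths that leave
the image raise `OutOfBoundsError` naming the offending position. Collinear
or too-short contours raise `DegenerateGeometryError`, as do coincident
poles (with the frame index, for traces). Background subtraction floors at
zero. Classifier ties break in the order central > bilateral > unilateral >
circumferential. Non-uniform frame spacing warns and proceeds on consecutive
pairs. Overlapping lumen polygons merge with a warning; reversed
NEBD/anaphase orderings and zero-duration tracks are errors.

## Problem sizes

The recovery experiments run at: 5 × 200 cells for classifier accuracy at
SNR 10 (≥ 95% required, typically 100%), 100 scenes for angle recovery
(50 voxel-quantised pole pairs + 50 acinus divisions, within 2°), 100 traces
for event-count recovery (exact), and analytic probes (bisection to 1e-9)
for the 10° event threshold and the 30° planar bound. The same experiments
back `mitoquant verify` and `scripts/acceptance.py`.
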