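# Methods

This note documents the detection model, its parameters and defaults, the
synthetic-scene generator, and the numerical/design choices made where the
design was genuinely open. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Detection model and assumptions

The detector formalizes a collision victim as a *sudden, persistent,
small* change: an object present in all N newest frames of a rolling
2N-frame stack and in none of the N oldest, with the transition at the
stack middle. This assumes the victim remains motionless after impact and
that frames are comparable pixel-by-pixel, which in turn requires
registration (the nacelle yaws with the wind) and global brightness
compensation (clouds). Animals that survive and move, or objects that
appear gradually, violate the model and are deliberately not detected.

Slow frame rates (Δt ≈ 10 s) make the "sudden" assumption cheap to test:
the object either is or is not there between two consecutive frames.
Scoring is index-based; Δt is metadata. Irregular intervals are tolerated
and logged, not rejected.

## Channels

* **LWIR** (thermal, ~640×512, ~11 cm/px): a fresh carcass is warmer than
  the ground; targets can be a single pixel, so region statistics must
  survive 1-px objects. The score is the difference of temporal medians
  of the two halves — the median of N = 5 values ignores up to 2 outlier
  frames per half, which is what a walking animal or a bird flying
  through produces. No brightness adjustment by default (the camera's
  gain control is internal).
* **VIS/NIR** (~1.5 cm/px): dark feathers on NIR-bright vegetation, so a
  carcass darkens tens to thousands of pixels. The score rewards a large
  middle-pair step (through a lookup table) and penalizes within-half
  temporal variation (moving grass alternates; a clean step does not).
  The score sign convention makes larger = more fatality-like; the step
  enters as a magnitude so the same code serves bright-on-dark scenes.

## Tunable parameters

| Parameter | Default | Units | Why |
| --- | --- | --- | --- |
| `half_size` N | 5 | frames | 10-frame stack; median of 5 tolerates 2 outliers |
| `frame_interval` | 10 | s | slow cadence; 100 s monitored window per stack |
| `alpha` | 1.0 | – | penalty weight of the VIS score; 1 weights a persistent alternation as heavily as the step it mimics |
| LUT anchors | (0,0),(70,70),(255,70) | gray → score | identity through the informative 15–30 band; differences above 70 are rarely fatalities and are compressed; the 255→70 endpoint is fixed |
| `block_size` | 31 | px | adaptive-threshold neighborhood: large vs. target, small vs. illumination gradients |
| threshold `offset` | 5 | gray | ≥3σ above the score noise floor for ~2 gray levels of sensor noise; smaller offsets let background pixels into candidate inner sets and corrupt the median statistics |
| `opening_radius` | VIS 1, LWIR 0 | px | opening removes specks on VIS; on LWIR it would erase legitimate 1-px targets |
| `dilate_iters` | VIS 3, LWIR 2 | iter | full-region reach; compact on LWIR so a 1–2 px target is not statistically diluted |
| `gap_iters` | 1 | iter | 1-px gap cleanly separates inner from outer |
| area limits | LWIR 1–100, VIS 4–4000 | px | expected carcass sizes at each ground sampling |
| discernibility thresholds | 11 | gray | inner median must exceed the old-frame and annulus medians by a contrast clearly above noise |
| surround score max | 2.9 | score | wind gusts raise scores over wide areas; a genuine target sits in a quiet surround (radius: 3× full-region bbox diagonal) |
| SSIM `C1`, `C2` | 1e-4, 0.03 | – (on [0,1] gray) | C2 keeps noise from dominating near-constant patches; C1 only guards the zero-mean degeneracy |
| `middle_sdiff_min` | 0.015 | – | see below |
| `side_sdiff_max` | 0.05 | – | movement between side frames (restless animal, wind) vetoes |
| `sdiff_quotient_min` | 3.0 | – | the middle change must dominate the largest side change |

### Why the middle-SDIFF floor is 0.015

With gray values normalized to [0, 1] and C2 = 0.03, the SSIM of two
nearly identical patches is pinned near 1 by the stabilizer: a target of
k px in an M-px full region with contrast d shifts the variance terms by
roughly k/M·d², which for a 2-px, 30-gray-level (d ≈ 0.12) object in a
~30-px region is ~1e-3 — far below C2. Genuine strike middle SDIFFs
therefore range from ~0.02 (1–2 px thermal targets) to ~0.5 (large
high-contrast targets), while noise-only pairs sit near 0.003–0.008.
A floor of 0.015 separates the two populations; discrimination against
disturbances is carried by the side ceiling and the quotient, not by the
floor alone. Setting the floor an order of magnitude higher would blind
the detector to exactly the small thermal targets the system exists for.

## Numerical choices

* Frames are processed in float64 end-to-end; quantization to 8 bits
  happens only at sequence I/O. Median matching is additive (an offset
  preserves the local contrasts the VIS score measures) and exactly
  idempotent; a multiplicative mode exists for experimentation.
* Histogram equalization is deliberately not used for brightness
  compensation: redistributing gray values based on another image
  destroys the meaning of absolute differences downstream.
* Registration estimates one transform per consecutive frame pair and
  composes along the chain to the newest frame; RANSAC uses a 2-px inlier
  band and reaches subpixel accuracy through the final least-squares refit
  over all inliers (the band is a robustness mechanism, not the accuracy
  target). A pair with too few keypoints breaks the chain; affected stack
  positions are skipped with a warning. Warped-in pixels are masked and
  excluded from every statistic; a candidate region masked beyond 20% in
  any frame is rejected with a logged reason.
* Population (not sample) variance and covariance in SSIM; `ssim(x, x)`
  is exactly 1.0 and symmetry is exact in floating point. A zero side
  maximum makes the SDIFF quotient +∞, which passes the quotient
  criterion iff the middle criterion passes.
* Preselection criteria run cheapest-first with early exit, so the
  surround statistic (a wide dilation) is only computed for candidates
  that already look plausible.
* Connectivity is 8-connected throughout; coordinates are 0-based
  (row, col). Ties in the adaptive threshold resolve to "not selected"
  (strict inequality).
* Duplicate suppression: an accepted candidate within 2× the region
  bbox diagonal of an event raised in the previous N stack positions is
  merged — the same dropped object stays visible in consecutive stacks.
  In practice the structural middle criterion already restricts events to
  the single stack whose middle pair straddles the appearance.
* `exclude_middle` (default off) drops the two frames straddling the
  midpoint from the half statistics (penalty sums, LWIR medians) to avoid
  catching the object mid-fall; the step term always uses the middle pair
  itself. Penalty normalization uses the actual pair count.

## Synthetic scenes: what they emulate, and what not

The generator renders, in event order: a static smoothed-noise vegetation
texture (keypoint-rich, as registration needs), global illumination steps,
spatially coherent zero-mean wind fluctuation over a contiguous area,
transient walkers, dwelling sitters with positional jitter, persistent
drops (thermal drops cool as `Δ0·exp(−t/τ)`, default τ = 300 s so a
30-gray-level object stays detectable ~5 min; VIS drops persist as
darkenings), per-frame affine nacelle jitter, and per-pixel Gaussian
sensor noise, quantized to 8 bits. Contrasts are magnitudes; the channel
fixes the sign (warm-on-cool LWIR, dark-on-bright VIS). Same spec + seed
is bit-identical.

The standard thermal benchmark (`benchmark_lwir_scene`) is a 64×64,
40-frame scene: a 3-px walker crosses early, a wind gust fluctuates a
corner late, and a 2-px drop of 30 gray levels lands at frame 18 on a
seed-derived position; the matched no-drop variant keeps the identical
distractors for false-positive measurement. Problem sizes (64×64, 40
frames, 20 seeds) keep a full benchmark run in seconds while leaving
~30 candidate evaluations per sequence.

Passing on these scenes demonstrates the decision logic — step detection,
median robustness, surround veto, structural discrimination — under
controlled noise. It does not demonstrate radiometric realism: no grass
blades, no directional emissivity, no gain-control artifacts, no rain,
no real nacelle vibration spectrum. Field sensitivities and false-positive
rates can only come from instrumented drop tests; the evaluation module
reproduces that arithmetic (sensitivity per stratum, false positives per
monitored hour, half-up rounding to the conventional printed precisions).

## Known limitations

* The VIS preselection thresholds are plausibility defaults scaled from
  the thermal operating point; they have not been validated against field
  imagery.
* Registration accuracy under real nacelle vibration (motion blur,
  rolling texture) is untested; the synthetic jitter model is rigid
  affine.
* An animal that sits still for the entire monitored window is
  indistinguishable from a fatality by construction; extending the stack
  window (larger N or Δt) is the designed mitigation, traded against
  thermal cooling of true targets.
* Duplicate suppression is positional; two genuinely distinct drops
  within 2× a region diagonal inside N stack positions would merge.
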