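# Methods

## Problem and model

An eye image in a non-cooperative setting contains a dark pupil inside a
mid-gray iris inside a bright sclera, disturbed by specular reflections
(near-saturated spots), eyelashes (thin dark strokes), partial eyelid
occlusion and off-angle gaze. Iris localization means recovering the two
near-concentric circles bounding the iris annulus. Both boundaries are
modeled as circles with continuous parameters `(x0, y0, r)`, searched on an
integer grid (1-px steps) by exhaustively maximizing a boundary-strength
objective; intensities are floats in [0, 1] end to end, with 8-bit
conversion only at file I/O.

### Objectives

*Integro-differential operator.* For a fixed center, the mean contour
intensity `m(r)` is computed over the integration arc at each candidate
radius (bilinear interpolation, out-of-frame samples excluded), its radial
derivative taken by central differences, smoothed with a 1-D Gaussian
(σ = 1 px, reflect padding), and the absolute value scored. It responds to
any circular step edge, but every sample on the contour contributes through
the mean, so a bright spot or lash crossing the contour shifts the argmax.

*Compensated radial-gradient operator.* Each of `n` rays contributes its
radial gradient `g_θ = I(θ, r+Δr) − I(θ, r)` minus the compensation
`C_θ = ½(|g_{θ+1} − g_θ| + |g_{θ−1} − g_θ|)`. On a clean circular edge all
`g` agree, `C ≡ 0`, and the score is the full gradient sum; an interference
spot that spikes `k` adjacent rays is taxed by comparable neighbor
differences at the spike's flanks, so its net contribution shrinks instead
of dominating the argmax. The score is `Σ(g − C)` over valid rays, rescaled
by `n / n_valid` so partially out-of-frame candidates stay comparable;
candidates with fewer than half their samples valid are rejected. The plain
gradient sum (no `C`) is kept as an ablation baseline.

### Two-stage search

1. **Inner boundary** — full-circle arc, `n = 32` (the pupillary contour is
   short), centers on an integer window of ±10 px around the detector-box
   center, radii from 8 px to 0.35·min(box side).
2. **Outer boundary** — two lateral 90° arcs, `[315°, 45°)` and
   `[135°, 225°)`, so eyelids and lashes stay off the integration path;
   `n = 256`; centers within ±3 px of the recovered inner center (the two
   boundaries are near-concentric but not exactly so); radii restricted to
   the open interval `1.2·rp < r < 0.5·max(rows, cols)` where `rp` is the
   recovered pupil radius and rows/cols are the detector-box sides. An empty
   interval is reported as a failure status rather than an exception.

Ties in the exhaustive maximum break toward the smaller radius, then
lexicographically by (cy, cx), making every search deterministic. Both
objectives always run over identical candidate grids, which is what makes
their comparison like-for-like.

### Denoising

Within the detector box (padded 10%; full-image mode by flag):
reflections first — pixels ≥ 0.90 (normalized), dilated 2 px to cover bloom
halos, filled by harmonic inward interpolation (Jacobi neighbor-averaging
sweeps over the masked pixels, tolerance 1e-5, cap 500 sweeps; pixels
outside the mask are untouched exactly) — then eyelashes, by grayscale
closing with a disk of radius 3 px at the 224-px reference scale (scaled
proportionally with image size). Closing is extensive and idempotent, which
the tests assert pixelwise. The threshold 0.90 reflects that specular points
are near-saturated in NIR imagery; both it and the element radius are
config-overridable.

### Coarse initialization

When no detector box is available, a fallback estimates one: inpaint
reflections, threshold at the 5th intensity percentile + 0.05, take the
largest connected dark component (≥ 50 px; rejected if the "dark" region is
most of the frame), and box its centroid with side six times the
component's equivalent radius. This stands in for an object detector and is
deliberately simple; it assumes a single dominant dark pupil in frame.

## Synthetic scenes

The generator renders, at 224×224 (the scale the pipeline defaults are tuned
to): a sclera background, an anti-aliased iris disk with a seeded radial
sinusoid texture plus smoothed noise (amplitude 0.05 — enough to give the
compensation factor nonzero within-iris gradients to cancel), a pupil disk
offset ≤ 2 px from the iris center, and optionally: near-saturated
reflection disks (radius 2–5 px, scattered over the iris including across
the limbus), 2-px-wide dark lash strokes angling down across the upper iris,
a straight eyelid edge covering a requested fraction of the iris, horizontal
axis compression for off-angle gaze (truth then records the equal-area
circle of the rendered ellipse), and Gaussian focus blur (σ 0.4–0.7 px).
Intensity levels (pupil ≈ 0.10, iris ≈ 0.45, sclera ≈ 0.85, ±0.03 jitter)
preserve the outward-increasing brightness the gradient sign convention
expects. The ground-truth bounding box is the integer hull of the iris
boundary plus one pixel of slack, the tightest box a detector could
plausibly regress; a box any tighter makes the outer radius interval clip
the limbus itself.

Default batch ranges: iris radius 50–75 px, pupil radius 0.25–0.45 of the
iris, centers within ±8 px of frame center. Strata: `clean` (texture only),
`noiseless` (texture off as well), `reflections` (3 spots), `eyelashes`
(12 strokes), `occlusion` (15–25%), `off_angle` (axis ratio 0.85–0.95),
`combined` (reflections + lashes + occlusion).

What the scenes do **not** emulate: real iris texture statistics (crypts,
furrows), NIR illumination physics, glasses refraction and frame glints,
camera noise, and elliptical *boundary* models (off-angle scenes are scored
against equal-area circles, so axis ratios well below 0.9 legitimately miss
at a 2-px tolerance — lateral arcs settle near the compressed horizontal
semi-axis). Passing the synthetic study therefore shows the operators and
search behave as designed under controlled interference, not that any
particular accuracy carries over to a specific camera or dataset.

## Numerical choices

- Bilinear interpolation for all contour samples; sample points within
  ~1.5 px of a hard step edge mix both sides (the bilinear footprint), which
  the hard-edge oracle tests account for by keeping sample radii clear of
  the edge.
- `Δr = 1` px radial step; `n/n_valid` rescaling for partial contours;
  gradient sign `outward_brighter` by default (dark-pupil imagery), flippable
  for visible-light material.
- At the open ends of partial arcs the missing neighbor term of `C` is
  replaced by the existing one; full circles wrap. Neighbors are likewise
  dropped per-sample when out of frame.
- The integro-differential derivative uses one-sided differences at the ends
  of the radius interval; invalid radii inside the interval are bridged by
  linear interpolation of `m(r)` before differentiation so the derivative
  stays local.
- Benchmark `mean_center_err` / `mean_radius_err` columns average the inner
  and outer boundary errors of scenes where the pipeline reported success.
- "Location accuracy" on synthetic scenes is defined as the hit rate under
  center error ≤ 2 px **and** radius error ≤ 2 px (inclusive); no standard
  pixel criterion exists, so these numbers are not comparable to accuracies
  reported on camera datasets.

## Design choices that were genuinely open

- The outer integration path ("90 degrees on the left and right sides") is
  read as 90° per side; a total of 90° (45° per side) is selectable via the
  arc config.
- The gradient-sum objective is left unnormalized (no `1/(2πr)`, no `1/n`)
  apart from the out-of-bounds rescaling; a radius bias toward
  higher-contrast rings on low-contrast images is possible in principle.
- Denoising order is reflections → lashes; both stages run before both
  search stages, and the outer stage searches the denoised image too.
- Outer-stage centers are searched at integer resolution; sub-pixel search
  would quadruple the grid for ≤ 0.5 px of expected gain at these scales.

## Problem sizes

The shipped study runs 100-scene batches per stratum (inner stage ≈ 441
centers × ~25 radii, outer ≈ 49 centers × ~15–40 radii per scene), which
gives recovery-rate estimates with a binomial standard error of ≤ 5 points
and completes in a few minutes on one CPU core.

## Known limitations

- Circle-only boundary model; strongly elliptical (far off-angle) irises
  and non-circular pupils (ocular disease) are out of scope.
- Compensation taxes any contour whose rays disagree — including a true
  limbus crossed by lashes or an eyelid edge. On rare scenes (~1 in 100
  combined-noise scenes) with a small pupil, the smooth residual
  pupillary-edge ring just above the `1.2·rp` bound pays no penalty and can
  outscore the taxed limbus, a miss the uncompensated sum avoids; under
  isolated interference (reflections) the ordering goes the other way, which
  is the regime the compensation exists for.
- The coarse pupil estimate fails on images whose darkest compact region is
  not the pupil (heavy shadows, hair); supply a detector box there.
- The harmonic fill flattens texture inside large masked regions; with
  reflection masks (a few px) this is invisible to the operators, but the
  routine is not a general-purpose inpainter.
- No detector is included: the package consumes boxes, it does not find eyes.
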