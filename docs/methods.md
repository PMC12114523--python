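# Methods

This note documents the models, conventions and numerical choices behind
`caliberkit`: what exactly is measured, how the synthetic phantoms that
validate the measurements are constructed, and where the design was
genuinely open.

## Coordinates, units and calibration

All analysis code speaks micrometres and minutes. Image coordinates are
(x, y) in µm with the origin at the center of pixel (row 0, col 0):
x = col·pixel_size, y = row·pixel_size. Pixel units never cross a module
boundary — `caliberkit.io` converts on the way in and out. Calibration
(µm/px, min/frame) must be supplied explicitly or through a JSON sidecar;
when both are present they must agree, and a missing calibration is a hard
error. Silent unit mistakes are the dominant failure mode in morphometry,
so nothing is ever guessed from image metadata alone.

## Centerlines and stations

Annotated axon paths are resampled at a fixed arc-length step (default
0.05 µm). Tangents come from central differences smoothed with a uniform
window of 0.5 µm — wide enough to suppress hand-annotation jitter at the
resampling scale, narrow enough to preserve curvature at the 3–5 µm radii
typical of these arbors; the window is forced to an odd sample count so
smoothing commutes with path reversal. Normals are tangents rotated 90°.

Distances from a branch point are **geodesic** (along the path), not
straight-line. For the gently curved segments involved the two conventions
differ by well under the measurement noise, but along-path is the
reproducible choice and is what the 3/4/5 µm segment offsets and the
station spacing use; a `euclidean` mode is provided for comparison.
Lengthwise stations are placed every 1 µm and any station strictly closer
than 3 µm to a branch-point anchor is dropped — a station at exactly 3 µm
is kept, reading the exclusion as a strict inequality.

## The caliber measurement

At a station, intensity is sampled along the perpendicular with cubic
spline interpolation (half-length 1.5 µm, spacing = pixel/2). Cubic rather
than bilinear interpolation matters: the extra blur of a triangle kernel
measurably worsens the peak pull-in of nearly merged membrane peaks at
small calibers.

Peak detection is two-stage:

1. **Selection** on a copy smoothed with a Gaussian of σ = 1.2 samples:
   local maxima with prominence ≥ 10% of the profile's dynamic range are
   candidates, and the candidate nearest the centerline on each side
   (strictly negative / strictly positive offset) forms the membrane pair.
   Nearest-opposite — not the two global maxima — rejects crosstalk from a
   neighboring axon crossing the scan window; the heavier smoothing
   suppresses shot-noise maxima inside the wide lumen of thick axons.
2. **Refinement** on a lightly smoothed copy (σ = 0.75 samples): each
   selected peak snaps to the nearest local maximum within ±3 samples and
   is interpolated with a 3-point parabola (shift clamped to ±½ sample;
   bias below 5% of the sample spacing for Gaussian-like peaks).

Caliber is the right-minus-left peak distance. A measurement is **flagged**
when the pair is unresolved (unimodal profile, or no qualifying peak on one
side) or the caliber falls below the resolution limit. The limit defaults
to 0.14 µm — an Airyscan-class lateral resolution figure, chosen here
because the imagery the package targets states only that such a limit
exists, not its value; it is a configuration field, not a constant. Flagged
measurements stay in output tables for transparency but never enter means,
SDs or %RSD, and a series with a flagged fraction strictly above 20% is
excluded outright.

Two peak-separation regimes are worth stating. For two Gaussian-blurred
membrane lines separated by c with effective blur σ_eff (PSF ⊕ pixelation ⊕
interpolation ≈ 0.073 µm at 0.04 µm pixels), the observed peak separation
underestimates c once c ≲ 3σ_eff, and the profile merges to unimodal near
c ≈ 2σ_eff. At c = 0.2 µm this pull-in is about −0.01 µm and is left
uncorrected (the measurement reports peak distance, not a deconvolved
diameter); below ≈ 0.15 µm the pair merges and the flag takes over. This is
why phantoms at 0.08 µm true caliber flag at ≈ 100%.

## Branch, dynamicity and dividing-cell metrics

Segment caliber at a branch point is the arithmetic mean over the 3/4/5 µm
offsets, using only non-flagged offsets; a segment with all offsets flagged
makes the whole triplet unmeasurable (and a below-resolution primary
excludes the branch point — the same exclusion a real acquisition would
apply). S1 is the thicker secondary; an exact tie keeps annotation order
and sets a flag. Derived quantities satisfy two identities used as
self-checks: symmetry ≡ norm_S2/norm_S1 and area taper ≡ (S1² + S2²)/P²
(the π/4 cancels). Cohort SEMs use the sample SD (n − 1).

Dynamicity summaries (mean, SD, %RSD) require at least 3 usable frames;
pearling requires at least 3 usable stations. Both use sample SD.

For the dividing-cell scene, stations are assigned to territories by
polygon containment of the centerline point, with ties at a border going to
the dividing cell (deterministic on rasterized borders). Border-to-border
length is the straight-line distance between the two extreme points where
the axon path crosses the territory's border. The round → flat transition
is the consecutive frame pair maximizing the border-length increase; ties
take the earliest pair and are flagged, and an all-decreasing schedule
still returns the least-negative step with a warning. Round/flat pairing
keeps only stations that lie on the dividing territory (or its daughters)
and are unflagged in both frames.

The arc path model treats the rounded cell as a circular segment: chord ℓ
(planar extent), sagitta h (height above the flat reference),
R = (ℓ²/4 + h²)/(2h), arc = 2R·asin(ℓ/(2R)) (reflex arc beyond a
semicircle), flat reference = the flat cell's planar length with the axon
assumed straight and pinned at the borders. A circular segment is the
minimal two-parameter shape consistent with "height and length" estimates;
the function is exposed so an elliptical variant can be substituted.

## Statistics

- **Paired permutation test**: statistic = mean difference; null = all
  independent sign flips. Exact enumeration (incremental doubling) for
  n ≤ 20, else seeded Monte Carlo with the observed assignment included —
  p = (b + 1)/(B + 1), never zero. Two-sided throughout (the comparisons
  this package feeds are reported two-sided and no direction is
  privileged). Exact two-sided p has granularity 1/2ⁿ⁻¹ with minimum
  2/2ⁿ.
- **Mann–Whitney U**: midranks for ties; exact by enumerating all
  C(n+m, n) labelings when n + m ≤ 14 (3003 labelings — sub-second), else
  a normal approximation with tie-corrected variance and continuity
  correction. The two-sided exact p counts labelings with
  |U − nm/2| ≥ |U_obs − nm/2|, which remains well defined under ties.
- **Estimation statistics**: paired mean difference with a seeded
  bootstrap 95% CI, BCa by default (bias correction from the bootstrap
  CDF at the observed mean, acceleration from the jackknife skewness) with
  a recorded percentile fallback when either is undefined. Constant
  differences give a zero-width CI.
- **Regression**: ordinary least squares, R² = 1 − SS_res/SS_tot; a
  zero-variance response reports R² = 0 with a degenerate flag.

Validated properties: exact modes agree with literal brute-force
enumeration to 1e-12; type-I error of the permutation test at nominal 0.05
(n = 10, standard normal differences) lands near the largest achievable
level below 0.05 (≈ 0.049); BCa coverage of a true paired mean difference
of 0.05 (SD 0.1, n = 30) is ≈ 95%.

## The phantom generator

The simulator exists to give every measurement a known answer; it emulates
the *geometry and photophysics that the line-scan measurement sees*, not
the full biology.

**Membrane model.** The axon is an infinitely thin label sheet at ±c(s)/2
along the centerline normal — two boundary curves in 2-D. This reproduces
the double-peak line-scan profile of membrane-targeted fluorophores.
Rendering is strictly 2-D: caliber is measured as in-plane peak
separation, so a 3-D optical model would add cost without changing what
the measurement sees.

**Caliber profiles.** c(s) = max(floor, baseline + Σ Gaussian pearls);
pearls are additive in *caliber* units (not intensity) so ground truth is
stated in the quantity being recovered. Negative amplitudes model
constrictions; the floor (0.04 µm) keeps the tube open.

**Optics and noise.** Boundary curves are rasterized with line-integrated
label density (bilinear scatter at a quarter-pixel step), convolved with an
isotropic Gaussian PSF (σ = 0.07 µm, an Airyscan-class lateral figure),
then Poisson noise on signal + background and Gaussian read noise.
Defaults: 20 000 photons/µm of membrane, background 10, read noise SD 2,
pixel 0.04 µm. These give a membrane-peak SNR of ≈ 13, the regime of
deconvolved Airyscan acquisitions, and were chosen so that the generator's
default conditions resemble imagery in which sub-0.1 µm peak separations
are plausibly measurable at all; at an order of magnitude fewer photons the
membrane peaks drown in background shot noise and no estimator recovers
them.

**Dynamics.** Four event classes modulate c(s, t) at a 5-min frame
interval: a traveling pearl (center advances at a fixed speed), focal
inflation/deflation (amplitude ramps up then down), segment
widening/narrowing (a span's baseline scales by a factor, with a 0.3 µm
spatial relaxation *outside* the span so the in-span ground truth is
exact), and a transient constriction (negative pearl on scheduled frames).
Time series with an exact prescribed %RSD use a skewed two-level caliber
schedule that stays resolvable even at 60% relative dynamicity.

**Dividing-cell scene.** Three cell territories along the axon; the
dividing cell's border-to-border extent follows a per-frame schedule
(shrinking while round, jumping as the daughters flatten), with the cell
channel drawing territory outlines and the axon channel gaining a
configurable caliber offset over the dividing territory (smoothed over
0.3 µm at the borders) and a uniform deflation from the flattening frame
onward.

**What the phantoms do not emulate** — and hence what passing tests do not
establish about real data: out-of-focus light and 3-D sectioning,
deconvolution artifacts, photobleaching, annotation error (centerlines are
exact), axon growth or branch formation, and neighboring-structure clutter
beyond a single crossing axon. Recovery numbers on phantoms are an upper
bound on real-data performance, which is why every filter (prominence,
resolution limit, series exclusion) is configurable.

## Problem sizes

Default study sizes were chosen to keep each analysis script and the whole
validation run in seconds-to-minutes on a laptop core while leaving
estimates well determined: 20-station recovery phantoms at six calibers,
branch cohorts of 6–12 scenes, 8–12-frame time lapses, 200-seed null-scene
calibration checks, 2000 simulations for type-I error and 500 for bootstrap
coverage.

## Known limitations

- Calibers within ≈ 2.5·σ_PSF of the merge point carry a small
  uncorrected pull-in bias (≤ 0.01–0.02 µm); a model-based deconvolution
  of the peak separation was deliberately left out to keep the measurement
  definition identical to the manual line-scan convention it reproduces.
- Time-series stations are re-anchored per frame from the annotation; there
  is no drift correction or tracking.
- The Mann–Whitney normal approximation is conservative for very small
  samples with heavy ties; exact mode covers n + m ≤ 14.
- The circular-arc path model is a geometric idealization; it makes no
  mechanical claim beyond the path-length ratio.
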