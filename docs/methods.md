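# Methods

This note records the models, estimators, defaults and numerical choices the
package implements, and what its synthetic-data tests do and do not
demonstrate about real microscopy data.

## Elastic model and traction reconstruction

The substrate is a linear-elastic, homogeneous, isotropic half-space; only
in-plane surface tractions and displacements are modelled (no z-component,
no finite-thickness correction). The Young's modulus is obtained from the
rheometer storage modulus as `E = 2G′(1+ν)` with ν = 0.45 by default
(polyacrylamide is nearly incompressible); ν = 0.5 exactly is rejected
because the in-plane Boussinesq formulation is singular there.

Forward model and inversion share one spectral kernel (`_boussinesq.py`).
The discrete transform pair is `u = ifft2(G(k) · fft2(t))` with
`k = 2π · fftfreq(n, spacing)`; with this convention no extra area factors
appear. Numerical choices:

- **Zero-padding.** Fields are zero-padded by an integer factor (default 4;
  8 where the far field matters) before the FFT because the real-space
  kernel decays only as 1/r. Padding is exact-integer so the padded
  geometry is predictable.
- **Uniform mode.** The k = 0 mode has infinite compliance (a rigid
  translation of the half-space is unobservable after drift correction) and
  is set to zero. Spectral solutions are therefore zero-mean representatives
  over the padded domain; comparisons against the closed-form point-force
  solution are made in that gauge (both fields de-meaned over the comparison
  region).
- **Point-like loads.** A point force represented as a single-node delta
  carries energy up to the Nyquist wavevector and rings; for validation
  against the closed form, a "point-like" load is a Gaussian of width 0.6
  grid spacings — narrow enough to act as a point beyond 3 spacings, wide
  enough (spectrum ~e^(−(πσ/d)²/2)) to suppress the ringing.
- **Regularization.** Default λ = 0, appropriate for noise-free synthetic
  fields and the round-trip identity; a zeroth-order Tikhonov inverse
  `t = (GᵀG + λ²I)⁻¹ Gᵀ u` is available for noisy image-derived fields.
  No automatic λ selection is built in; the round trip
  forward → inverse is identity to <5% relative RMS away from boundaries
  (the boundary ring is affected by truncating the slowly decaying
  displacement at the crop edge).

## Image processing

Z-stacks are median-filtered per slice (3×3) and maximum-intensity
projected. Drift is estimated per frame from the subpixel cross-correlation
peak of each 1/5 × 1/5 corner region against the first frame; the
componentwise median of the four corner shifts is robust to one disturbed
corner, and flat (featureless) corners are excluded with a warning. The
zero-stress reference image is the pixelwise temporal median — valid only
when each pixel is unstressed in most frames, i.e. when the cell moves
across the field during the recording; a static cell leaves its deformation
in the reference.

Displacements are measured on a 0.75 μm grid: per node, a template around
the node is cut from the reference and matched in the frame by normalized
cross-correlation (window default 4× grid spacing, search margin default
half a window — raise `max_shift` if displacements exceed ~1.5 μm), with
three-point Gaussian subpixel peak interpolation. Estimates then pass a
normalized-median outlier test (3×3 neighbourhood, threshold
2×median-residual + 0.1 μm) and are smoothed/filled by Gaussian-weighted
normalized convolution (kernel 1.5× grid spacing). The correlation peak
height is kept as a per-node quality score. Self-consistency on rendered
bead images (≈1 bead/μm², 0.3 μm spots, 0.25 μm pixels) recovers smooth
imposed fields to <20% relative RMS; fields with features at the window
scale are low-pass filtered by the method — a physical resolution limit,
not an implementation artifact.

One coordinate convention is used throughout: arrays are indexed
`[iy, ix]`, y increases with row index, and displacement/stress components
follow the same axes. No image-style y-flip exists anywhere; TIFF output
will appear vertically mirrored in viewers that draw row 0 on top.

## Localization and trajectory

Noise is estimated from the same 1/5 × 1/5 corner convention as drift
correction; the threshold is exactly 3× the median corner maximum, making
the suprathreshold set invariant under rescaling of the whole map. The
growth-cone position is the polygon-area centroid of the convex hull of all
suprathreshold nodes (all nodes, not only local maxima — a more stable
hull); fewer than three non-collinear points fall back to the vertex mean.
Frames with an empty suprathreshold set are invalid.

Smoothing uses a centered moving average with window
`W = max(3, round_to_odd(T_smooth/Δt))`, `T_smooth = 360 s`, so Δt =
120–180 s recordings get a 3-point window and Δt = 2 s recordings get 181
points; edges use shrunken symmetric windows; invalid frames are ignored.
Velocities are forward differences of the smoothed positions. The stall
filter removes both steps of any pair with a strictly negative velocity dot
product (zero dot product is kept).

## Co-moving frame and averaging

Each map is translated so the hull centroid is the origin and rotated so
the velocity maps onto (−1, 0); stress vectors rotate with the grid.
Resampling is bilinear onto a regular grid at the original spacing spanning
±15 μm by default; output nodes mapping outside the source grid carry NaN
and count 0 (never zero-filled). The average divides the per-node
accumulated sum by the per-node count, so partially covered borders stay
unbiased. Net force is the vector sum of stress times cell area
(1 Pa·μm² = 1 pN); the sign convention is traction exerted by the cell on
the substrate, with the axon tension equal and opposite to the net traction
force. Flank peaks of the average field are the |mean stress| maxima in the
y > 0 and y < 0 half-planes.

## Peak tracking and lifetimes

Peaks are 3×3 local maxima of stress magnitude above the frame threshold,
kept in decreasing stress order with suppression within `d_min` (default
2 μm; ties broken toward the lower node index) and refined to subgrid
precision by a quadratic fit. Linking: a peak A joins a peak B of the next
frame only if B is A's nearest frame-n+1 peak and their distance is within
the link distance (default 2 μm at Δt = 2 s); candidates are processed in
increasing-distance order and each B is consumed once; if A's nearest B was
taken by a closer competitor, A's track ends. There is no gap closing, and
no manual editing stage — close same-flank foci therefore merge into single
long tracks, which is the main failure mode on crowded data.

A track's lifetime is (detections − 1) × Δt, so a single-frame appearance
has lifetime 0 and lands in the sub-15 s class that the display range
[15, 600] s hides (all lifetimes are retained internally). The lifetime fit
is unweighted least squares of log(count) against bin center over
30–150 s, excluding empty bins; τ = −1/slope, flagged invalid for
non-negative slopes. A maximum-likelihood fit of the doubly truncated
exponential over the same window is provided as a cross-check. No
finite-observation censoring correction is applied; at 1800 s recordings
the exponential window 30–150 s is far from the record length and the
correction would be negligible.

## Tension statistics

F(t) is the magnitude of the per-frame net force. The autocorrelation uses
the biased estimator — centered products summed over all available origins,
divided by the full length n and the series variance — so R(0) = 1 exactly
and white-noise fluctuations stay below ~1/√n at every lag. Negative R
values are reported; only the log-linear fit (window 10–80 s, lags to
480 s) excludes them. The MSD averages squared increments per lag (lags to
900 s, clipped to half the duration) and is normalized by μ², which makes a
saturation value above 1 the signature of fluctuations larger than the
mean; the power-law exponent is the log-log slope over 2–200 s. No second
normalization is applied to R beyond σ².

**Estimator bias at short records.** For a mean-reverting signal with
correlation time τ_c observed for T, the sample autocorrelation is biased
low by ≈ (1−ρ(τ))·2τ_c/T because the series mean is estimated from the same
record. At T ≈ 19 τ_c (1800 s with τ_c = 95 s) the log-linear 10–80 s fit
recovers ≈70–80 s instead of 95 s, with large seed-to-seed scatter. The
plain estimator is retained deliberately — it is what the printed formula
specifies — and recovered decay times from single half-hour recordings
should be read as lower bounds with ~±25 s uncertainty.

The mean-reverting tension model is an exact-discretization
Ornstein–Uhlenbeck process (stationary initialization); the
fractional-noise mode adds `scale · B_H(t)` with fBm generated by Cholesky
factorization of the exact covariance (factor cached per (n, dt, H)), so
the theoretical MSD exponent is 2H (3/7 for H = 3/14). Tension magnitudes
are clamped at 5% of the mean in the map generator; the pure samplers are
unclamped apart from a floor at zero where a magnitude is required.

## Synthetic generator: defaults and what they represent

Field 48 × 48 μm at 0.75 μm spacing; Δt = 2 s (high-resolution condition;
use 120–180 s for trajectory-regime studies); speed 0.02 μm/s (3.6 μm per
180 s); focus birth rate 0.1/s with mean lifetime 38 s (≈4 active foci);
focus peak stress 150 Pa, width 1.5 μm, flanks at ±5 μm lateral offset with
1 μm placement jitter; neck 3 μm behind the footprint center, width 3 μm;
mean tension 1 nN with 0.5 nN OU fluctuations at τ_c = 95 s; observation
noise 2 Pa per component, made zero-sum per frame so the ground-truth net
force equals the field integral exactly. The "true position" ground truth
is the centroid of the three traction centers (two flanks + neck), which is
the quantity the hull method estimates. The tension-balance component sits
at the neck and absorbs whatever force the foci do not supply; its
amplitude therefore fluctuates with focus number.

The generator does **not** emulate filopodia, retrograde flow, cell-shape
changes, photobleaching, focus drift in z, or spatially correlated camera
noise. Passing recovery tests on it demonstrates that the estimators are
correct and correctly calibrated for the stated stochastic model — not that
real images of real growth cones will be measured with the same accuracy.

## Problem sizes used in the test suite

Statistical recovery tests use 5000 lifetimes, 20 seeds × 900-sample
tension series, and a 60-frame low-resolution cone on a 180 × 50 μm field;
image-based round trips use 18–36 μm fields. These sizes put sampling error
comfortably inside each test's tolerance while keeping the whole suite
around 20 s on one CPU.

## Known limitations

- 2D in-plane TFM only; no z-displacements, no finite gel thickness.
- λ = 0 FTTC amplifies grid-scale PIV noise; use the Tikhonov mode for
  image-derived fields and choose λ by inspection (no automatic L-curve).
- The temporal-median reference fails for cells that do not move relative
  to their footprint during the recording.
- Track merging of nearby foci inflates fitted lifetimes on crowded data;
  there is no merge/split handling.
- Autocorrelation decay times from single short recordings are biased low
  (see above); ensemble averaging across recordings reduces variance but
  not this bias.
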