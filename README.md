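# gctfm — growth-cone traction force microscopy

`gctfm` turns time-lapse images of fluorescent beads embedded in a soft
polyacrylamide substrate into a quantitative, dynamic picture of the forces a
neuronal growth cone exerts while it advances. It was built around the regime
of dorsal-root-ganglion (DRG) neurites on 150–400 Pa gels: traction maps are
reconstructed per frame, the growth cone is located and tracked from its own
stress "footprint", stress fields are averaged in the co-moving frame of the
cone, transient stress peaks are tracked and their lifetimes fitted, and the
net force — the tension carried by the axon — is analysed as a stochastic
signal.

It is aimed at researchers doing neuronal traction force microscopy (TFM) who
want a scriptable, fully tested pipeline, and at modellers who need a
ground-truthed synthetic data generator to validate analysis choices.

## The science in brief

**Traction reconstruction (FTTC).** The substrate is treated as an elastic
half-space with Young's modulus `E = 2G′(1+ν)` (Poisson ratio ν = 0.45 for
polyacrylamide). Bead displacements **u** relate to the traction field **t**
through the Boussinesq–Cerruti Green's tensor; in Fourier space

```
u~(k) = G(k) t~(k),   G(k) = 2(1+ν)/(E k³) [ (1−ν)k² + ν ky²    −ν kx ky
                                             −ν kx ky    (1−ν)k² + ν kx² ]
```

so the traction is recovered by inverting the 2×2 tensor per wavevector
(zero-padded, optional Tikhonov term λ, uniform mode zeroed).

**Stress-based tracking.** Per frame, the noise level `S_noise` is the median
of the four stress-magnitude maxima in the 1/5 × 1/5 corner regions, and the
detection threshold is `S_threshold = 3 S_noise`. The growth-cone position is
the area centroid of the convex hull of all suprathreshold nodes. Positions
are smoothed with a centered moving window (width set by the frame interval
Δt), differenced into velocities `v_n = (r_{n+1} − r_n)/Δt`, and steps with
`v_n · v_{n+1} < 0` (stalls) are excluded.

**Co-moving average.** Each map is rotated about the centroid so the velocity
points along −x and the rotated maps are accumulated node-wise. For an
advancing cone this reveals a force-dipole-like pattern: strong flank maxima
pointing inward toward the neck, plus an unbalanced rearward component — the
axon tension.

**Fluctuation statistics.** Stress peaks are linked frame-to-frame by a
nearest-neighbour rule and their lifetime histogram is fitted log-linearly
over 30–150 s. The tension magnitude F(t) is summarized by its normalized
autocorrelation `R(τ) = ⟨(F(t)−μ)(F(t+τ)−μ)⟩/σ²` (exponential fit over
10–80 s) and by the mean squared displacement
`MSD(τ) = ⟨(F(t+τ)−F(t))²⟩/μ²` (power-law fit over 2–200 s, saturation at
`2σ²/μ²` for bounded dynamics).

**Synthetic generator.** `simulate_traction_series` produces a growth cone
advancing at ~0.02 μm/s whose traction is a superposition of flank stress
foci (Poisson births, exponential lifetimes, vectors pointing toward the
neck), a neck component enforcing a prescribed stochastic tension
(mean-reverting, or fractional noise with configurable Hurst exponent), and
observation noise — with full ground truth for every downstream stage.

## Worked example

```python
import numpy as np
from gctfm import (SimulationConfig, simulate_traction_series, track_growth_cone,
                   tension_series, autocorrelation, fit_autocorr_decay,
                   msd, fit_msd_exponent, estimate_noise, detect_peaks,
                   link_peaks, lifetime_histogram, fit_exponential_lifetime)

cfg = SimulationConfig(n_frames=900, dt=2.0, seed=42)   # 30 min at 2 s resolution
maps, truth = simulate_traction_series(cfg)

ts = tension_series(maps)
print(f"mean tension      : {ts.mean:.2f} nN (sd {ts.std:.2f} nN)")
print(f"autocorr decay    : {fit_autocorr_decay(autocorrelation(ts)):.0f} s")
print(f"MSD exponent      : {fit_msd_exponent(msd(ts, max_lag=890.0)):.2f}")

dets = [detect_peaks(tm, estimate_noise(tm), frame=i) for i, tm in enumerate(maps)]
tracks = link_peaks(dets, max_link_distance=2.0, dt=cfg.dt)
fit = fit_exponential_lifetime(lifetime_histogram(tracks, bin_width=10.0))
print(f"peak tracks       : {len(tracks)} (lifetime decay {fit.tau:.0f} s)")

traj = track_growth_cone(maps, cfg.dt)
err = np.linalg.norm(traj.positions - truth.centroid, axis=1)
print(f"localization error: {np.nanmean(err):.2f} um (mean over {len(maps)} frames)")
```

prints

```
mean tension      : 0.85 nN (sd 0.39 nN)
autocorr decay    : 50 s
MSD exponent      : 0.63
peak tracks       : 140 (lifetime decay 60 s)
localization error: 1.04 um (mean over 900 frames)
```

The tension of this realization fluctuates around 0.85 nN with fluctuations
half as large as the mean. The fitted autocorrelation decay (50 s here) is a
noisy, downward-biased estimate of the generator's 95 s correlation time —
a single 30-minute recording carries only ~19 correlation times of data (see
`docs/methods.md`). The MSD exponent 0.63 reflects mean-reverting dynamics
between the diffusive (1) and saturated (0) regimes over the 2–200 s window.
Peak tracking finds 140 tracks whose lifetime fit (60 s) sits above the
generated 38 s mean because nearby same-flank foci merge into longer tracks.
Localization lands within ~1 μm (≈1.4 grid spacings) of the true footprint
center.

A command-line interface mirrors the stages
(`gctfm simulate | reconstruct | localize | average | peaks | tension | run |
report`), e.g.

```bash
gctfm run --out myrun --seed 7     # simulate + full analysis + manifest
gctfm report --run-dir myrun      # six-panel summary figure
```

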