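"""Ground-truthed synthetic growth-cone traction data.

The generator emulates the regime observed for advancing dorsal-root-ganglion
(DRG) growth cones on soft (150–400 Pa) polyacrylamide substrates: a growth
cone advancing at ~0.02 μm/s whose traction field is a superposition of

* localized contractile stress foci on the two flanks, oriented toward the
  neck (where the axon joins the growth cone), born as a Poisson process and
  dying after exponentially distributed lifetimes (mean ``tau_life``),
* a neck-region component that balances the books so that the net traction
  force equals a prescribed, stochastically fluctuating rearward tension
  (mean-reverting by default, optionally fractional noise for sub-diffusive
  scaling tests), and
* i.i.d. observation noise (made zero-sum per frame so the ground-truth net
  force remains exact).

Everything downstream (FTTC round trips, localization, co-moving averaging,
peak tracking, tension statistics) is tested against the returned
:class:`GroundTruth`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field as dfield
from typing import Literal, Optional, Sequence

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from ._boussinesq import apply_forward
from .fields import PA_UM2_TO_NN, DisplacementField, TractionMap, make_grid

__all__ = [
    "SimulationConfig",
    "FocusRecord",
    "GroundTruth",
    "sample_focus_lifetimes",
    "ou_series",
    "fbm_series",
    "simulate_traction_series",
    "forward_displacement",
    "render_bead_images",
]


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic growth-cone recording.

    Defaults correspond to the high-time-resolution condition (Δt = 2 s);
    pass ``dt=120`` or ``dt=180`` for the low-resolution trajectory regime.
    Lengths in μm, times in s, stresses in Pa, forces in nN.
    """

    field_size: tuple[float, float] = (48.0, 48.0)
    spacing: float = 0.75
    dt: float = 2.0
    n_frames: int = 120
    speed: float = 0.02              # μm/s, ~3.6 μm per 180 s
    heading_deg: float = 0.0         # direction of motion in the lab frame
    start: Optional[tuple[float, float]] = None
    birth_rate: float = 0.1          # foci/s
    tau_life: float = 38.0           # s, mean focus lifetime
    focus_stress: float = 150.0      # Pa, peak stress per focus
    focus_width: float = 1.5         # μm, Gaussian sigma of a focus
    flank_offset: tuple[float, float] = (0.0, 5.0)   # (forward, lateral) μm
    position_jitter: float = 1.0     # μm, sd of focus placement around a flank
    neck_offset: float = 3.0         # μm behind the footprint center
    neck_width: float = 3.0          # μm, sigma of the balancing component
    mean_tension: float = 1.0        # nN
    tension_sigma: float = 0.5       # nN (OU sd, or fBm increment scale)
    tension_tau: float = 95.0        # s, OU correlation time
    tension_model: Literal["ou", "fbm"] = "ou"
    hurst: float = 3.0 / 14.0        # fBm Hurst exponent (MSD exponent 2H)
    noise_pa: float = 2.0            # Pa, observation noise sd per component
    seed: int = 0

    def __post_init__(self) -> None:
        positive = {
            "spacing": self.spacing,
            "dt": self.dt,
            "n_frames": self.n_frames,
            "tau_life": self.tau_life,
            "focus_stress": self.focus_stress,
            "focus_width": self.focus_width,
            "neck_width": self.neck_width,
            "mean_tension": self.mean_tension,
            "tension_tau": self.tension_tau,
        }
        for name, v in positive.items():
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and positive, got {v!r}")
        nonneg = {
            "speed": self.speed,
            "birth_rate": self.birth_rate,
            "tension_sigma": self.tension_sigma,
            "noise_pa": self.noise_pa,
            "position_jitter": self.position_jitter,
            "neck_offset": self.neck_offset,
        }
        for name, v in nonneg.items():
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and non-negative, got {v!r}")
        if not all(np.isfinite(self.field_size)) or min(self.field_size) <= 0:
            raise ValueError("field_size must be positive")
        if not (0.0 < self.hurst < 1.0):
            raise ValueError("hurst must lie in (0, 1)")
        if self.tension_model not in ("ou", "fbm"):
            raise ValueError("tension_model must be 'ou' or 'fbm'")


@dataclass
class FocusRecord:
    """One generated stress focus and its full life history."""

    birth_time: float
    death_time: float
    birth_frame: int
    death_frame: int
    side: int                      # +1 left flank, -1 right flank
    offset: tuple[float, float]    # cone-frame offset from the footprint center
    amplitude: float               # Pa

    @property
    def lifetime(self) -> float:
        return self.death_time - self.birth_time


@dataclass
class GroundTruth:
    """Oracle values for every recovery test on a simulated series."""

    centroid: np.ndarray      # (N, 2) μm, footprint center per frame
    velocity: np.ndarray      # (N, 2) μm/s
    net_force: np.ndarray     # (N, 2) nN
    tension: np.ndarray       # (N,) nN, |net force|
    foci: list[FocusRecord] = dfield(default_factory=list)

    def __post_init__(self) -> None:
        for f in self.foci:
            if f.death_frame < f.birth_frame:
                raise ValueError("focus death frame precedes birth frame")


def sample_focus_lifetimes(
    n: int, tau_life: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` focus lifetimes (s) from Exponential(``tau_life``)."""
    if tau_life <= 0:
        raise ValueError("tau_life must be positive")
    return rng.exponential(tau_life, size=int(n))


def ou_series(
    n: int,
    dt: float,
    mean: float,
    sigma: float,
    tau: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Stationary mean-reverting (Ornstein–Uhlenbeck) series, exact AR(1).

    Autocorrelation is exp(-τ/``tau``); the first sample is drawn from the
    stationary distribution N(mean, sigma²).
    """
    if tau <= 0 or dt <= 0:
        raise ValueError("dt and tau must be positive")
    a = math.exp(-dt / tau)
    x = np.empty(int(n))
    x[0] = mean + sigma * rng.standard_normal()
    innov = sigma * math.sqrt(1.0 - a * a) * rng.standard_normal(int(n) - 1)
    for k in range(1, int(n)):
        x[k] = mean + a * (x[k - 1] - mean) + innov[k - 1]
    return x


def fbm_series(
    n: int, dt: float, hurst: float, rng: np.random.Generator
) -> np.ndarray:
    """Fractional Brownian motion B_H at times k·dt, via Cholesky.

    Var[B_H(t)] = t^(2H), so the mean squared increment over lag τ is
    τ^(2H) — sub-diffusive for H < 1/2.
    """
    if not (0.0 < hurst < 1.0):
        raise ValueError("hurst must lie in (0, 1)")
    key = (int(n), float(dt), float(hurst))
    chol = _FBM_CHOLESKY_CACHE.get(key)
    if chol is None:
        t = dt * np.arange(1, int(n))
        h2 = 2.0 * hurst
        tt = t[:, None]
        ss = t[None, :]
        cov = 0.5 * (tt ** h2 + ss ** h2 - np.abs(tt - ss) ** h2)
        chol = np.linalg.cholesky(cov + 1e-12 * np.eye(len(t)))
        if len(_FBM_CHOLESKY_CACHE) > 4:
            _FBM_CHOLESKY_CACHE.clear()
        _FBM_CHOLESKY_CACHE[key] = chol
    out = np.zeros(int(n))
    out[1:] = chol @ rng.standard_normal(int(n) - 1)
    return out


_FBM_CHOLESKY_CACHE: dict[tuple, np.ndarray] = {}


def _rotation(theta: float) -> np.ndarray:
    c, s = math.cos(theta), math.sin(theta)
    return np.array([[c, -s], [s, c]])


def _tension_magnitude(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    if cfg.tension_model == "ou":
        f = ou_series(
            cfg.n_frames, cfg.dt, cfg.mean_tension, cfg.tension_sigma,
            cfg.tension_tau, rng,
        )
    else:
        f = cfg.mean_tension + cfg.tension_sigma * fbm_series(
            cfg.n_frames, cfg.dt, cfg.hurst, rng
        )
    # tension is a magnitude; clamp rare negative excursions
    return np.maximum(f, 0.05 * cfg.mean_tension)


def _spawn_foci(cfg: SimulationConfig, rng: np.random.Generator) -> list[FocusRecord]:
    total_t = cfg.n_frames * cfg.dt
    foci: list[FocusRecord] = []

    def make(birth: float, life: float) -> FocusRecord:
        death = birth + life
        side = 1 if rng.random() < 0.5 else -1
        off = (
            cfg.flank_offset[0] + cfg.position_jitter * rng.standard_normal(),
            side * cfg.flank_offset[1] + cfg.position_jitter * rng.standard_normal(),
        )
        bf = min(cfg.n_frames - 1, max(0, math.ceil(birth / cfg.dt)))
        # a focus whose whole life falls between samples is never observed;
        # its frame interval collapses to the birth frame
        df = min(cfg.n_frames - 1, max(bf, int(death / cfg.dt)))
        return FocusRecord(
            birth_time=birth,
            death_time=death,
            birth_frame=bf,
            death_frame=df,
            side=side,
            offset=off,
            amplitude=cfg.focus_stress,
        )

    # foci alive at t=0 (stationary count, residual lifetimes by memorylessness)
    n0 = rng.poisson(cfg.birth_rate * cfg.tau_life)
    for _ in range(n0):
        foci.append(make(0.0, float(rng.exponential(cfg.tau_life))))
    # Poisson births during the recording
    n_births = rng.poisson(cfg.birth_rate * total_t)
    births = np.sort(rng.uniform(0.0, total_t, size=n_births))
    lifetimes = sample_focus_lifetimes(n_births, cfg.tau_life, rng)
    for b, life in zip(births, lifetimes):
        foci.append(make(float(b), float(life)))
    return foci


def simulate_traction_series(
    cfg: SimulationConfig,
) -> tuple[list[TractionMap], GroundTruth]:
    """Generate ``cfg.n_frames`` traction maps plus full ground truth.

    Each map is the sum of the active flank foci (Gaussian stress spots
    pointing toward the instantaneous neck position), a neck component that
    enforces the prescribed net tension exactly, and zero-sum observation
    noise.  The ground-truth net force therefore equals the areal integral
    of each returned map to numerical precision.
    """
    rng = np.random.default_rng(cfg.seed)
    x, y = make_grid(cfg.field_size, cfg.spacing)
    xx, yy = np.meshgrid(x, y)
    area = cfg.spacing ** 2

    theta = math.radians(cfg.heading_deg)
    heading = np.array([math.cos(theta), math.sin(theta)])
    rot = _rotation(theta)
    travel = cfg.speed * cfg.dt * (cfg.n_frames - 1)
    if cfg.start is not None:
        start = np.asarray(cfg.start, float)
    else:
        center = np.array([cfg.field_size[0] / 2.0, cfg.field_size[1] / 2.0])
        start = center - rot @ np.array([travel / 2.0, 0.0])
    times = cfg.dt * np.arange(cfg.n_frames)
    centroids = start[None, :] + cfg.speed * times[:, None] * heading[None, :]

    margin = cfg.flank_offset[1] + cfg.neck_offset + 3 * cfg.focus_width
    if (centroids.min() < margin - 1e-9) or (
        (np.array(cfg.field_size) - centroids.max(axis=0)).min() < margin - 1e-9
    ):
        warnings.warn("growth-cone path comes close to the field boundary")

    tension = _tension_magnitude(cfg, rng)
    foci = _spawn_foci(cfg, rng)
    neck_local = np.array([-cfg.neck_offset, 0.0])

    maps: list[TractionMap] = []
    net = np.empty((cfg.n_frames, 2))
    for n, t in enumerate(times):
        c = centroids[n]
        tx = np.zeros_like(xx)
        ty = np.zeros_like(xx)
        neck_pos = c + rot @ neck_local
        for f in foci:
            if not (f.birth_time <= t < f.death_time):
                continue
            pos = c + rot @ np.asarray(f.offset)
            d2 = (xx - pos[0]) ** 2 + (yy - pos[1]) ** 2
            blob = f.amplitude * np.exp(-d2 / (2.0 * cfg.focus_width ** 2))
            direction = neck_pos - pos
            direction = direction / max(np.linalg.norm(direction), 1e-12)
            tx += blob * direction[0]
            ty += blob * direction[1]
        # balance: prescribed net force (pN), rearward along -heading
        desired = -heading * tension[n] / PA_UM2_TO_NN  # nN → pN
        current = np.array([tx.sum(), ty.sum()]) * area
        g = np.exp(
            -((xx - neck_pos[0]) ** 2 + (yy - neck_pos[1]) ** 2)
            / (2.0 * cfg.neck_width ** 2)
        )
        coef = (desired - current) / (g.sum() * area)
        tx += g * coef[0]
        ty += g * coef[1]
        if cfg.noise_pa > 0:
            ex = rng.normal(0.0, cfg.noise_pa, xx.shape)
            ey = rng.normal(0.0, cfg.noise_pa, xx.shape)
            tx += ex - ex.mean()
            ty += ey - ey.mean()
        net[n] = desired * PA_UM2_TO_NN
        maps.append(TractionMap(x=x, y=y, t=float(t), tx=tx, ty=ty))

    # the "true position" is the center of the traction footprint (what the
    # convex-hull method estimates): centroid of the three traction centers
    footprint_offset = rot @ np.array(
        [(2.0 * cfg.flank_offset[0] - cfg.neck_offset) / 3.0, 0.0]
    )
    truth = GroundTruth(
        centroid=centroids + footprint_offset[None, :],
        velocity=np.tile(cfg.speed * heading, (cfg.n_frames, 1)),
        net_force=net,
        tension=tension.copy(),
        foci=foci,
    )
    return maps, truth


def forward_displacement(
    traction: TractionMap, E: float, nu: float, pad_factor: int = 4
) -> DisplacementField:
    """Substrate surface displacement produced by a traction map.

    Spectral convolution with the Boussinesq Green's tensor, zero-padded by
    ``pad_factor`` to suppress wrap-around.  The k = 0 mode (rigid
    translation) is unobservable and set to zero.
    """
    ux, uy = apply_forward(
        traction.tx, traction.ty, traction.spacing, E, nu, pad_factor
    )
    return DisplacementField(
        x=traction.x, y=traction.y, t=traction.t, ux=ux, uy=uy
    )


def render_bead_images(
    displacements: Sequence[DisplacementField],
    bead_density: float = 1.0,
    spot_sigma: float = 0.3,
    pixel_size: float = 0.25,
    noise: float = 0.02,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Render a fluorescent-bead image series from a displacement series.

    Beads are placed uniformly in the reference (zero-stress) configuration
    at ``bead_density`` beads/μm², advected by the bilinearly interpolated
    displacement field of each frame, and rendered as unit-amplitude
    Gaussian spots of width ``spot_sigma`` μm with additive Gaussian noise.

    Returns ``(frames, reference)`` where frames has shape (N, H, W) and
    reference is the noise-free zero-displacement image.
    """
    if bead_density <= 0 or spot_sigma <= 0 or pixel_size <= 0:
        raise ValueError("bead_density, spot_sigma and pixel_size must be positive")
    d0 = displacements[0]
    window_area = (4.0 * d0.spacing) ** 2
    if bead_density * window_area < 4.0:
        warnings.warn(
            "bead density too low to constrain the displacement grid "
            f"({bead_density * window_area:.1f} beads per correlation window)"
        )
    rng = np.random.default_rng(seed)
    lx = float(d0.x[-1] - d0.x[0])
    ly = float(d0.y[-1] - d0.y[0])
    n_beads = rng.poisson(bead_density * lx * ly)
    bead_xy = np.column_stack(
        [
            d0.x[0] + rng.uniform(0.0, lx, n_beads),
            d0.y[0] + rng.uniform(0.0, ly, n_beads),
        ]
    )
    w = int(round(lx / pixel_size)) + 1
    h = int(round(ly / pixel_size)) + 1

    def render(points: np.ndarray) -> np.ndarray:
        img = np.zeros((h, w))
        rad = max(2, int(math.ceil(4.0 * spot_sigma / pixel_size)))
        for px, py in points:
            cx = (px - d0.x[0]) / pixel_size
            cy = (py - d0.y[0]) / pixel_size
            ix, iy = int(round(cx)), int(round(cy))
            x0, x1 = max(0, ix - rad), min(w, ix + rad + 1)
            y0, y1 = max(0, iy - rad), min(h, iy + rad + 1)
            if x0 >= x1 or y0 >= y1:
                continue
            gx = np.arange(x0, x1) - cx
            gy = np.arange(y0, y1) - cy
            img[y0:y1, x0:x1] += np.exp(
                -(gx[None, :] ** 2 + gy[:, None] ** 2)
                * (pixel_size ** 2)
                / (2.0 * spot_sigma ** 2)
            )
        return img

    reference = render(bead_xy)
    frames = np.empty((len(displacements), h, w))
    for i, d in enumerate(displacements):
        fux = RegularGridInterpolator(
            (d.y, d.x), d.ux, bounds_error=False, fill_value=0.0
        )
        fuy = RegularGridInterpolator(
            (d.y, d.x), d.uy, bounds_error=False, fill_value=0.0
        )
        pts = bead_xy[:, ::-1]  # (y, x) ordering for the interpolator
        moved = bead_xy + np.column_stack([fux(pts), fuy(pts)])
        img = render(moved)
        if noise > 0:
            img = img + rng.normal(0.0, noise, img.shape)
        frames[i] = img
    return frames, reference
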