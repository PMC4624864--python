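"""Growth-cone localization and trajectory construction from traction maps.

The growth cone leaves a traction "footprint": per frame, a noise level is
estimated from the four corner regions of the stress map, the map is
thresholded at three times that level, and the centroid of the convex hull
of all suprathreshold nodes is taken as the growth-cone position.  The
position series is smoothed with a centered moving window, differenced into
velocities, and steps where consecutive velocities oppose each other
(stalls) are excluded.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .fields import TractionMap

__all__ = [
    "NoiseEstimate",
    "Trajectory",
    "estimate_noise",
    "locate_growth_cone",
    "smooth_trajectory",
    "compute_velocities",
    "stall_filter",
    "track_growth_cone",
]

#: threshold is this multiple of the corner-derived noise level
THRESHOLD_MULTIPLIER = 3.0


@dataclass(frozen=True)
class NoiseEstimate:
    """Per-frame stress noise level and detection threshold (Pa)."""

    s_noise: float
    s_threshold: float
    corner_maxima: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        if not math.isclose(self.s_threshold, THRESHOLD_MULTIPLIER * self.s_noise):
            raise ValueError("threshold must equal 3 × noise")


def estimate_noise(tm: TractionMap, frac: int = 5) -> NoiseEstimate:
    """Noise from the cell-free corners of the traction map.

    The corner regions are the four 1/5 × 1/5 sub-grids; the noise level is
    the median of their four stress-magnitude maxima (mean of the middle
    two), and the threshold is three times the noise.
    """
    ny, nx = tm.shape
    if ny < 10 or nx < 10:
        raise ValueError("map must be at least 10×10 nodes")
    mag = tm.magnitude()
    ch, cw = ny // frac, nx // frac
    corners = (
        mag[:ch, :cw],
        mag[:ch, nx - cw:],
        mag[ny - ch:, :cw],
        mag[ny - ch:, nx - cw:],
    )
    maxima = tuple(float(c.max()) for c in corners)
    s_noise = float(np.median(maxima))
    return NoiseEstimate(
        s_noise=s_noise,
        s_threshold=THRESHOLD_MULTIPLIER * s_noise,
        corner_maxima=maxima,
    )


def _polygon_centroid(points: np.ndarray) -> np.ndarray:
    """Area centroid of the convex hull of ``points`` (N ≥ 1, 2D).

    Falls back to the vertex mean for fewer than three non-collinear points.
    """
    pts = np.atleast_2d(np.asarray(points, float))
    if len(pts) < 3:
        return pts.mean(axis=0)
    try:
        hull = ConvexHull(pts)
    except QhullError:  # collinear
        return pts.mean(axis=0)
    v = pts[hull.vertices]
    x, y = v[:, 0], v[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    area = 0.5 * cross.sum()
    if abs(area) < 1e-12:
        return v.mean(axis=0)
    cx = np.sum((x + xn) * cross) / (6.0 * area)
    cy = np.sum((y + yn) * cross) / (6.0 * area)
    return np.array([cx, cy])


def locate_growth_cone(
    tm: TractionMap, noise: NoiseEstimate
) -> Optional[np.ndarray]:
    """Centroid of the convex hull of suprathreshold nodes (μm).

    Returns None when no node exceeds the threshold (frame invalid).
    """
    mask = tm.magnitude() > noise.s_threshold
    if not mask.any():
        return None
    xx, yy = tm.meshgrid()
    pts = np.column_stack([xx[mask], yy[mask]])
    return _polygon_centroid(pts)


def _window_size(t_smooth: float, dt: float) -> int:
    w = int(round(t_smooth / dt))
    if w % 2 == 0:
        w += 1
    return max(3, w)


def smooth_trajectory(
    positions: np.ndarray, dt: float, t_smooth: float = 360.0
) -> np.ndarray:
    """Centered moving-average smoothing of the position series.

    The window is W = max(3, round-to-odd(t_smooth / dt)) frames, so
    low-time-resolution recordings (Δt = 120–180 s) get a 3-point window
    while Δt = 2 s recordings get ~181 points.  Edges use shrunken
    symmetric windows; NaN (invalid) positions are ignored.
    """
    pos = np.asarray(positions, float)
    valid = np.isfinite(pos).all(axis=1)
    if valid.sum() < 3:
        raise ValueError("need at least three valid positions")
    n = len(pos)
    w = _window_size(t_smooth, dt)
    if w > n:
        warnings.warn(f"smoothing window {w} exceeds series length {n}; clipped")
        w = n if n % 2 == 1 else n - 1
    half = w // 2
    out = np.full_like(pos, np.nan)
    for i in range(n):
        if not valid[i]:
            continue
        k = min(half, i, n - 1 - i)  # shrunken symmetric window at the edges
        sl = slice(i - k, i + k + 1)
        m = valid[sl]
        out[i] = pos[sl][m].mean(axis=0)
    return out


def compute_velocities(positions: np.ndarray, dt: float) -> np.ndarray:
    """Forward-difference velocities v_n = (r_{n+1} - r_n) / Δt (μm/s)."""
    pos = np.asarray(positions, float)
    if len(pos) < 2:
        raise ValueError("need at least two positions")
    return np.diff(pos, axis=0) / dt


def stall_filter(velocities: np.ndarray) -> np.ndarray:
    """Validity mask over velocity steps excluding stalls.

    Whenever v_n · v_{n+1} < 0 (strict), both steps n and n+1 are marked
    invalid — the growth cone reversed rather than advanced.  Steps with
    undefined (NaN) velocity are invalid as well.
    """
    v = np.asarray(velocities, float)
    if len(v) < 2:
        raise ValueError("need at least two velocities")
    valid = np.isfinite(v).all(axis=1)
    dots = np.einsum("ij,ij->i", v[:-1], v[1:])
    for n, d in enumerate(dots):
        if np.isfinite(d) and d < 0:
            valid[n] = False
            valid[n + 1] = False
    return valid


@dataclass
class Trajectory:
    """Growth-cone positions, smoothed positions, velocities and validity.

    ``positions`` rows are NaN where localization failed.  ``velocities``
    has N-1 rows; ``valid_step[n]`` marks whether step n survives the stall
    filter and has defined positions at both ends.
    """

    t: np.ndarray
    positions: np.ndarray
    smoothed: np.ndarray
    velocities: np.ndarray
    valid_step: np.ndarray
    dt: float

    @property
    def n_frames(self) -> int:
        return len(self.positions)


def track_growth_cone(
    maps: Sequence[TractionMap],
    dt: float,
    t_smooth: float = 360.0,
) -> Trajectory:
    """Full localization chain over a traction-map series.

    Per frame: corner-noise threshold → convex-hull centroid; then window
    smoothing, forward-difference velocities and the stall filter.
    """
    positions = np.full((len(maps), 2), np.nan)
    for i, tm in enumerate(maps):
        noise = estimate_noise(tm)
        pos = locate_growth_cone(tm, noise)
        if pos is not None:
            positions[i] = pos
    smoothed = smooth_trajectory(positions, dt, t_smooth)
    velocities = compute_velocities(smoothed, dt)
    valid = stall_filter(velocities)
    t = dt * np.arange(len(maps)) + (maps[0].t if maps else 0.0)
    return Trajectory(
        t=t,
        positions=positions,
        smoothed=smoothed,
        velocities=velocities,
        valid_step=valid,
        dt=dt,
    )
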