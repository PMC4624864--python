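"""Co-moving-frame transformation and stress-field averaging.

Each traction map is rotated about the growth-cone centroid so that the
instantaneous velocity points along the negative x-axis; in that frame the
neck/axon lies toward +x.  Valid rotated frames are accumulated node-wise
into an average stress field, whose net force should be parallel to the
x-axis for a steadily advancing growth cone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage as ndi

from .fields import PA_UM2_TO_NN, TractionMap, net_force

__all__ = [
    "AverageStressField",
    "rotate_map_to_frame",
    "average_frames",
    "net_force",
    "flank_peaks",
]


def rotate_map_to_frame(
    tm: TractionMap,
    centroid: np.ndarray,
    velocity: np.ndarray,
    half_width: float = 15.0,
) -> TractionMap:
    """Resample a traction map into the growth cone's reference frame.

    Grid positions are translated so the centroid is the origin and rotated
    by the angle that maps the velocity direction onto (-1, 0); stress
    vectors are rotated by the same angle.  The output is a regular grid at
    the original spacing spanning ±``half_width`` μm, filled by bilinear
    interpolation; nodes that map outside the source grid are NaN (they
    carry no sample, never zero).
    """
    v = np.asarray(velocity, float)
    speed = np.linalg.norm(v)
    if not speed > 0:
        raise ValueError("zero velocity: frame should have been stall-filtered")
    c = np.asarray(centroid, float)
    if not (
        tm.x[0] <= c[0] <= tm.x[-1] and tm.y[0] <= c[1] <= tm.y[-1]
    ):
        raise ValueError("centroid outside map bounds")
    phi = math.atan2(v[1], v[0])
    psi = math.pi - phi  # rotation taking the velocity onto (-1, 0)
    cs, sn = math.cos(psi), math.sin(psi)

    d = tm.spacing
    n = int(round(half_width / d))
    axis = d * np.arange(-n, n + 1)
    qx, qy = np.meshgrid(axis, axis)
    # source (lab) position of each output node: p = c + R(-psi) q
    px = c[0] + cs * qx + sn * qy
    py = c[1] - sn * qx + cs * qy
    rows = (py - tm.y[0]) / d
    cols = (px - tm.x[0]) / d
    coords = np.stack([rows.ravel(), cols.ravel()])
    tx_s = ndi.map_coordinates(
        tm.tx, coords, order=1, mode="constant", cval=np.nan
    ).reshape(qx.shape)
    ty_s = ndi.map_coordinates(
        tm.ty, coords, order=1, mode="constant", cval=np.nan
    ).reshape(qx.shape)
    # rotate the sampled stress vectors into the cone frame
    tx_f = cs * tx_s - sn * ty_s
    ty_f = sn * tx_s + cs * ty_s
    return TractionMap(x=axis, y=axis, t=tm.t, tx=tx_f, ty=ty_f)


@dataclass
class AverageStressField:
    """Node-wise mean stress field in the co-moving frame.

    ``count`` is the number of frames contributing at each node; the mean is
    accumulated-sum / count, NaN where no frame covered the node.
    ``net`` is the net force (nN) of the mean field.
    """

    x: np.ndarray
    y: np.ndarray
    tx_mean: np.ndarray
    ty_mean: np.ndarray
    count: np.ndarray
    net: np.ndarray
    n_frames: int

    @property
    def spacing(self) -> float:
        return float(self.x[1] - self.x[0])

    def as_traction_map(self) -> TractionMap:
        return TractionMap(
            x=self.x,
            y=self.y,
            tx=np.nan_to_num(self.tx_mean),
            ty=np.nan_to_num(self.ty_mean),
        )


def average_frames(
    rotated: Sequence[TractionMap],
    valid: Optional[Sequence[bool]] = None,
) -> AverageStressField:
    """Accumulate rotated maps into the average stress field.

    Only frames with ``valid`` True contribute.  Per-node counts (rather
    than division by N) keep partially covered border nodes unbiased.
    """
    if valid is None:
        valid = [True] * len(rotated)
    frames = [tm for tm, ok in zip(rotated, valid) if ok]
    if not frames:
        raise ValueError("no valid frames to average")
    ref = frames[0]
    sx = np.zeros(ref.shape)
    sy = np.zeros(ref.shape)
    cnt = np.zeros(ref.shape, int)
    for tm in frames:
        if not tm.congruent(ref):
            raise ValueError("rotated maps must share one grid")
        ok = np.isfinite(tm.tx) & np.isfinite(tm.ty)
        sx[ok] += tm.tx[ok]
        sy[ok] += tm.ty[ok]
        cnt += ok
    with np.errstate(invalid="ignore", divide="ignore"):
        mx = np.where(cnt > 0, sx / cnt, np.nan)
        my = np.where(cnt > 0, sy / cnt, np.nan)
    area = ref.cell_area
    net = np.array(
        [np.nansum(mx) * area * PA_UM2_TO_NN, np.nansum(my) * area * PA_UM2_TO_NN]
    )
    return AverageStressField(
        x=ref.x,
        y=ref.y,
        tx_mean=mx,
        ty_mean=my,
        count=cnt,
        net=net,
        n_frames=len(frames),
    )


def flank_peaks(avg: AverageStressField) -> list[dict]:
    """Locations and stress vectors of the |mean stress| maximum in each
    half-plane (y > 0 and y < 0) of the average field.

    For a symmetric advancing growth cone these are the two flank stress
    maxima; their vectors should point inward toward the neck (+x side).
    """
    mag = np.hypot(
        np.nan_to_num(avg.tx_mean), np.nan_to_num(avg.ty_mean)
    )
    xx, yy = np.meshgrid(avg.x, avg.y)
    peaks = []
    for sign in (1, -1):
        half = (yy * sign) > 0
        if not half.any():
            continue
        m = np.where(half, mag, -np.inf)
        iy, ix = np.unravel_index(np.argmax(m), m.shape)
        peaks.append(
            {
                "side": sign,
                "position": np.array([avg.x[ix], avg.y[iy]]),
                "stress": np.array([avg.tx_mean[iy, ix], avg.ty_mean[iy, ix]]),
                "magnitude": float(mag[iy, ix]),
            }
        )
    return peaks
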