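"""Stress-peak detection, frame-to-frame linking, and lifetime statistics.

Localized traction maxima correspond to transient adhesion engagements.
Peaks are detected per frame as suprathreshold local maxima, linked through
time by a deterministic nearest-neighbour rule (a peak A in one frame joins
a peak B in the next only if B is A's closest peak and lies within the link
distance), and the distribution of track lifetimes is summarized by a
histogram and a log-linear exponential fit over a fixed time window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage as ndi

from .fields import TractionMap
from .localize import NoiseEstimate

__all__ = [
    "PeakDetection",
    "PeakTrack",
    "LifetimeHistogram",
    "LifetimeFit",
    "detect_peaks",
    "link_peaks",
    "lifetime_histogram",
    "fit_exponential_lifetime",
    "fit_exponential_lifetime_mle",
]

#: histogram display range (s); shorter/longer-lived peaks are kept
#: internally but excluded from display, matching the published histogram
DISPLAY_RANGE = (15.0, 600.0)
#: default window (s) for the log-linear exponential fit
FIT_WINDOW = (30.0, 150.0)


@dataclass(frozen=True)
class PeakDetection:
    frame: int
    position: tuple[float, float]  # μm, subgrid-refined
    stress: float                  # Pa, magnitude at the peak node


@dataclass
class PeakTrack:
    """A stress peak followed over strictly consecutive frames."""

    detections: list[PeakDetection]
    dt: float

    def __post_init__(self) -> None:
        frames = [d.frame for d in self.detections]
        if any(b - a != 1 for a, b in zip(frames, frames[1:])):
            raise ValueError("track frames must be strictly consecutive")

    @property
    def birth_time(self) -> float:
        return self.detections[0].frame * self.dt

    @property
    def death_time(self) -> float:
        return self.detections[-1].frame * self.dt

    @property
    def lifetime(self) -> float:
        """(number of detections - 1) × Δt; a single appearance lives 0 s."""
        return (len(self.detections) - 1) * self.dt


def _refine(mag: np.ndarray, iy: int, ix: int) -> tuple[float, float]:
    """Quadratic subgrid refinement of a local maximum, in node units."""
    out = [float(ix), float(iy)]
    for axis, i in ((0, ix), (1, iy)):
        if axis == 0:
            if 0 < ix < mag.shape[1] - 1:
                f0, f1, f2 = mag[iy, ix - 1], mag[iy, ix], mag[iy, ix + 1]
            else:
                continue
        else:
            if 0 < iy < mag.shape[0] - 1:
                f0, f1, f2 = mag[iy - 1, ix], mag[iy, ix], mag[iy + 1, ix]
            else:
                continue
        denom = f0 - 2.0 * f1 + f2
        if abs(denom) > 1e-12:
            out[axis] += 0.5 * (f0 - f2) / denom
    return out[0], out[1]


def detect_peaks(
    tm: TractionMap,
    noise: NoiseEstimate,
    d_min: float = 2.0,
    frame: int = 0,
) -> list[PeakDetection]:
    """Suprathreshold local maxima of stress magnitude, with suppression.

    Local maxima (3×3 neighbourhood) above the frame threshold are kept in
    decreasing stress order; any maximum within ``d_min`` μm of an already
    kept (stronger) one is suppressed, ties broken toward the lower node
    index.  Kept peaks get subgrid positions by quadratic refinement.
    """
    mag = tm.magnitude()
    local_max = mag == ndi.maximum_filter(mag, size=3)
    mask = local_max & (mag > noise.s_threshold)
    iys, ixs = np.nonzero(mask)
    order = sorted(
        range(len(iys)), key=lambda k: (-mag[iys[k], ixs[k]], iys[k], ixs[k])
    )
    kept: list[tuple[float, float, float]] = []  # (x, y, stress) node coords
    d = tm.spacing
    for k in order:
        iy, ix = int(iys[k]), int(ixs[k])
        x0, y0 = tm.x[ix], tm.y[iy]
        if any(math.hypot(x0 - px, y0 - py) < d_min for px, py, _ in kept):
            continue
        kept.append((x0, y0, float(mag[iy, ix])))
    detections = []
    for x0, y0, s in kept:
        ix = int(round((x0 - tm.x[0]) / d))
        iy = int(round((y0 - tm.y[0]) / d))
        fx, fy = _refine(mag, iy, ix)
        detections.append(
            PeakDetection(
                frame=frame,
                position=(tm.x[0] + fx * d, tm.y[0] + fy * d),
                stress=s,
            )
        )
    return detections


def link_peaks(
    detections_per_frame: Sequence[Sequence[PeakDetection]],
    max_link_distance: float = 2.0,
    dt: float = 2.0,
) -> list[PeakTrack]:
    """Greedy nearest-neighbour linking of per-frame detections.

    A peak A in frame n is associated with a peak B in frame n+1 only if B
    is the closest of all frame-n+1 peaks to A and their distance does not
    exceed ``max_link_distance``.  Candidate links are processed in order of
    increasing distance and each B is consumed at most once; if A's closest
    B was already consumed by a closer A, A's track ends.  Unmatched
    detections start new tracks.  No gap closing: a missed detection
    terminates a track.
    """
    open_tracks: list[list[PeakDetection]] = []
    closed: list[list[PeakDetection]] = []
    for n, dets in enumerate(detections_per_frame):
        dets = list(dets)
        if n == 0:
            open_tracks = [[d] for d in dets]
            continue
        candidates = []
        for ti, track in enumerate(open_tracks):
            a = np.asarray(track[-1].position)
            if not dets:
                continue
            dists = [float(np.linalg.norm(a - np.asarray(b.position))) for b in dets]
            j = int(np.argmin(dists))
            if dists[j] <= max_link_distance:
                candidates.append((dists[j], ti, j))
        consumed: set[int] = set()
        matched: set[int] = set()
        for dist, ti, j in sorted(candidates, key=lambda c: (c[0], c[1])):
            if ti in matched or j in consumed:
                continue  # closest B gone → A stays unmatched
            open_tracks[ti].append(dets[j])
            consumed.add(j)
            matched.add(ti)
        next_open = [open_tracks[ti] for ti in matched]
        closed.extend(
            open_tracks[ti] for ti in range(len(open_tracks)) if ti not in matched
        )
        next_open.extend([d] for j, d in enumerate(dets) if j not in consumed)
        open_tracks = next_open
    closed.extend(open_tracks)
    # keep chronological birth order for reproducibility
    closed.sort(key=lambda tr: (tr[0].frame, tr[0].position))
    return [PeakTrack(detections=tr, dt=dt) for tr in closed]


@dataclass
class LifetimeHistogram:
    """Lifetime histogram; full range retained, display range flagged."""

    edges: np.ndarray
    counts: np.ndarray
    bin_width: float
    display_range: tuple[float, float] = DISPLAY_RANGE

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    def display_mask(self) -> np.ndarray:
        lo, hi = self.display_range
        return (self.centers >= lo) & (self.centers <= hi)


def lifetime_histogram(
    lifetimes_or_tracks: Sequence, bin_width: float = 10.0
) -> LifetimeHistogram:
    """Histogram of track lifetimes (s).

    Accepts either PeakTracks or raw lifetimes.  Bins cover [0, max) at
    ``bin_width``; all lifetimes are counted internally even if outside the
    published display range [15, 600] s.
    """
    items = list(lifetimes_or_tracks)
    if not items:
        raise ValueError("need at least one track or lifetime")
    if isinstance(items[0], PeakTrack):
        lifetimes = np.array([t.lifetime for t in items])
    else:
        lifetimes = np.asarray(items, float)
    top = bin_width * (math.floor(lifetimes.max() / bin_width) + 1)
    edges = np.arange(0.0, top + 0.5 * bin_width, bin_width)
    counts, _ = np.histogram(lifetimes, bins=edges)
    return LifetimeHistogram(edges=edges, counts=counts, bin_width=bin_width)


@dataclass
class LifetimeFit:
    """Log-linear exponential fit of the lifetime histogram."""

    tau: float                       # s, decay time (-1/slope)
    stderr: float                    # s, propagated slope standard error
    window: tuple[float, float]
    n_bins: int
    valid: bool


def fit_exponential_lifetime(
    hist: LifetimeHistogram, window: tuple[float, float] = FIT_WINDOW
) -> LifetimeFit:
    """Least-squares line on (bin center, log count) over the fit window.

    Zero-count bins are excluded; at least three nonzero bins are required.
    A non-negative slope flags the fit invalid (no decay).
    """
    centers = hist.centers
    sel = (centers >= window[0]) & (centers <= window[1]) & (hist.counts > 0)
    if sel.sum() < 3:
        raise ValueError("need at least three nonzero bins inside the window")
    xw = centers[sel]
    yw = np.log(hist.counts[sel].astype(float))
    (slope, _), cov = np.polyfit(xw, yw, 1, cov=True)
    se_slope = math.sqrt(max(cov[0, 0], 0.0))
    if slope >= 0:
        return LifetimeFit(
            tau=math.inf, stderr=math.inf, window=window,
            n_bins=int(sel.sum()), valid=False,
        )
    tau = -1.0 / slope
    return LifetimeFit(
        tau=tau,
        stderr=se_slope / slope ** 2,
        window=window,
        n_bins=int(sel.sum()),
        valid=True,
    )


def fit_exponential_lifetime_mle(
    lifetimes: np.ndarray, window: tuple[float, float] = FIT_WINDOW
) -> float:
    """Cross-check mode: maximum-likelihood decay time of a doubly
    truncated exponential restricted to the fit window.

    Solves the truncated-exponential score equation for τ by bisection.
    """
    lt = np.asarray(lifetimes, float)
    a, b = window
    x = lt[(lt >= a) & (lt <= b)]
    if x.size < 3:
        raise ValueError("need at least three lifetimes inside the window")
    m = x.mean() - a
    span = b - a

    def bias(tau: float) -> float:
        z = span / tau
        return tau - span / math.expm1(z)  # E[x - a] for truncated exp

    lo, hi = 1e-3, 1e6
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if bias(mid) < m:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
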