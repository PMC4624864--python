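"""Bead images → traction maps: preprocessing, drift correction, reference
construction, PIV displacement measurement, and FTTC inversion.

The processing chain follows standard Fourier-transform traction cytometry
on an elastic half-space: per-slice median filter and maximum-intensity
projection, rigid drift correction from the four image corners, a temporal
median reference image, windowed normalized cross-correlation on a 0.75 μm
grid with subpixel peak refinement and Gaussian-weighted smoothing, and
spectral inversion of the Boussinesq Green's tensor.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import match_template
from skimage.registration import phase_cross_correlation

from ._boussinesq import apply_inverse
from .fields import DisplacementField, TractionMap

__all__ = [
    "GelSubstrate",
    "youngs_modulus_from_storage",
    "project_stack",
    "correct_drift",
    "compute_reference_image",
    "measure_displacements",
    "compute_traction",
]


def youngs_modulus_from_storage(g_prime: float, nu: float) -> float:
    """Young's modulus from the shear storage modulus: E = 2 G′ (1 + ν)."""
    if g_prime < 0:
        raise ValueError("storage modulus must be non-negative")
    if not (0.0 <= nu < 0.5):
        raise ValueError("Poisson ratio must lie in [0, 0.5)")
    return 2.0 * g_prime * (1.0 + nu)


@dataclass(frozen=True)
class GelSubstrate:
    """Elastic parameters of the polyacrylamide substrate.

    Constructed either from a rheometer storage modulus G′ (E = 2G′(1+ν))
    or directly from E.  The Poisson ratio default 0.45 is the value used
    for nearly incompressible polyacrylamide.
    """

    E: float
    nu: float = 0.45

    def __post_init__(self) -> None:
        if self.E < 0:
            raise ValueError("Young's modulus must be non-negative")
        if not (0.0 <= self.nu < 0.5):
            raise ValueError("Poisson ratio must lie in [0, 0.5)")

    @classmethod
    def from_storage_modulus(cls, g_prime: float, nu: float = 0.45) -> "GelSubstrate":
        return cls(E=youngs_modulus_from_storage(g_prime, nu), nu=nu)

    @property
    def g_prime(self) -> float:
        return self.E / (2.0 * (1.0 + self.nu))


def project_stack(zstack: np.ndarray, median_size: int = 3) -> np.ndarray:
    """Median-filter each slice, then maximum-intensity project to 2D.

    ``zstack`` may be (nz, h, w) or already 2D, in which case only the
    median filter is applied.
    """
    stack = np.asarray(zstack, float)
    if stack.ndim == 2:
        stack = stack[None]
    if stack.ndim != 3 or stack.shape[0] < 1:
        raise ValueError("expected a (nz, h, w) stack with at least one slice")
    filtered = np.stack(
        [ndi.median_filter(s, size=median_size) for s in stack]
    )
    return filtered.max(axis=0)


def _corner_slices(shape: tuple[int, int], frac: int = 5):
    h, w = shape
    ch, cw = h // frac, w // frac
    return [
        (slice(0, ch), slice(0, cw)),
        (slice(0, ch), slice(w - cw, w)),
        (slice(h - ch, h), slice(0, cw)),
        (slice(h - ch, h), slice(w - cw, w)),
    ]


def correct_drift(
    series: np.ndarray, upsample: int = 20
) -> tuple[np.ndarray, np.ndarray]:
    """Remove rigid stage drift relative to the first frame.

    For each frame the shift of each of the four 1/5 × 1/5 corner regions
    with respect to the first frame is found from the cross-correlation
    peak (subpixel); the componentwise median of the four shifts is taken
    as the frame drift, and the frame is translated by its negation.

    Returns ``(corrected series, shifts)`` with shifts of shape (N, 2) in
    (row, col) pixels.
    """
    series = np.asarray(series, float)
    if series.ndim != 3 or series.shape[0] < 2:
        raise ValueError("need at least two frames of equal size")
    ref = series[0]
    corners = _corner_slices(ref.shape[1:] if ref.ndim == 3 else ref.shape)
    shifts = np.zeros((series.shape[0], 2))
    corrected = series.copy()
    for n in range(1, series.shape[0]):
        estimates = []
        for sl in corners:
            a, b = ref[sl], series[n][sl]
            if a.std() < 1e-12 or b.std() < 1e-12:
                warnings.warn(f"flat corner region in frame {n}; excluded")
                continue
            shift, _, _ = phase_cross_correlation(a, b, upsample_factor=upsample)
            estimates.append(-np.asarray(shift))  # drift of frame n vs frame 0
        if not estimates:
            warnings.warn(f"no usable corner in frame {n}; zero shift assumed")
            drift = np.zeros(2)
        else:
            drift = np.median(np.asarray(estimates), axis=0)
        shifts[n] = drift
        corrected[n] = ndi.shift(series[n], -drift, order=1, mode="nearest")
    return corrected, shifts


def compute_reference_image(series: np.ndarray) -> np.ndarray:
    """Zero-stress reference image: pixelwise temporal median.

    Beads spend most frames near their rest position, so the median over
    time removes transient stress-induced excursions.
    """
    series = np.asarray(series, float)
    if series.ndim != 3 or series.shape[0] < 3:
        raise ValueError("need at least three frames for a temporal median")
    return np.median(series, axis=0)


def _subpixel_offset(corr: np.ndarray, peak: tuple[int, int]) -> np.ndarray:
    """Three-point subpixel peak interpolation along each axis.

    Uses the Gaussian (log-parabolic) estimator standard in PIV when the
    three samples are positive, falling back to a plain parabola.
    """
    out = np.array(peak, float)
    for ax in range(2):
        i = peak[ax]
        if 0 < i < corr.shape[ax] - 1:
            idx = list(peak)
            idx[ax] = i - 1
            f0 = corr[tuple(idx)]
            f1 = corr[peak]
            idx[ax] = i + 1
            f2 = corr[tuple(idx)]
            if f0 > 0 and f1 > 0 and f2 > 0:
                f0, f1, f2 = math.log(f0), math.log(f1), math.log(f2)
            denom = f0 - 2.0 * f1 + f2
            if abs(denom) > 1e-12:
                delta = 0.5 * (f0 - f2) / denom
                out[ax] += float(np.clip(delta, -1.0, 1.0))
    return out


def measure_displacements(
    frame: np.ndarray,
    reference: np.ndarray,
    pixel_size: float,
    grid_spacing: float = 0.75,
    window: float | None = None,
    max_shift: float | None = None,
    smooth_sigma: float | None = None,
    min_quality: float = 0.3,
    t: float = 0.0,
) -> DisplacementField:
    """Bead displacements frame↔reference on a regular grid.

    Per grid node a template around the node is cut from the reference and
    matched in a search window of the frame by normalized cross-correlation;
    the correlation peak is refined to subpixel precision by quadratic
    interpolation.  The scattered estimates are then smoothed onto the grid
    by Gaussian-weighted interpolation (kernel ``smooth_sigma``, default
    1.5 × grid spacing); low-texture or low-correlation nodes are flagged
    and filled from their neighbours.  ``quality`` is the correlation peak
    height.

    Defaults: ``window`` = 4 × grid spacing, ``max_shift`` = window / 2.
    """
    frame = np.asarray(frame, float)
    reference = np.asarray(reference, float)
    if frame.shape != reference.shape:
        raise ValueError("frame and reference must be congruent")
    if window is None:
        window = 4.0 * grid_spacing
    if max_shift is None:
        max_shift = window / 2.0
    if smooth_sigma is None:
        smooth_sigma = 1.5 * grid_spacing
    half = max(2, int(round(window / pixel_size / 2)))
    marg = max(2, int(round(max_shift / pixel_size)))
    h, w = frame.shape
    xs = grid_spacing * np.arange(int((w - 1) * pixel_size / grid_spacing) + 1)
    ys = grid_spacing * np.arange(int((h - 1) * pixel_size / grid_spacing) + 1)
    ux = np.full((ys.size, xs.size), np.nan)
    uy = np.full((ys.size, xs.size), np.nan)
    quality = np.zeros((ys.size, xs.size))
    for iy, yv in enumerate(ys):
        r = int(round(yv / pixel_size))
        for ix, xv in enumerate(xs):
            c = int(round(xv / pixel_size))
            r0, r1 = r - half, r + half + 1
            c0, c1 = c - half, c + half + 1
            if r0 < 0 or c0 < 0 or r1 > h or c1 > w:
                # clip template to the image; skip if too small
                r0, r1 = max(0, r0), min(h, r1)
                c0, c1 = max(0, c0), min(w, c1)
                if (r1 - r0) < half or (c1 - c0) < half:
                    continue
            templ = reference[r0:r1, c0:c1]
            if templ.std() < 1e-9:
                continue
            s_r0, s_r1 = max(0, r0 - marg), min(h, r1 + marg)
            s_c0, s_c1 = max(0, c0 - marg), min(w, c1 + marg)
            search = frame[s_r0:s_r1, s_c0:s_c1]
            if search.std() < 1e-9:
                continue
            corr = match_template(search, templ)
            peak = np.unravel_index(np.argmax(corr), corr.shape)
            sub = _subpixel_offset(corr, peak)
            # displacement = found template origin minus zero-shift origin
            dy = (sub[0] + s_r0) - r0
            dx = (sub[1] + s_c0) - c0
            q = float(corr[peak])
            if q < min_quality:
                continue
            ux[iy, ix] = dx * pixel_size
            uy[iy, ix] = dy * pixel_size
            quality[iy, ix] = q
    # normalized-median outlier validation (standard PIV practice):
    # flag nodes deviating from the local 3x3 median by more than a few
    # median residuals before smoothing fills them from neighbours
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN neighbourhoods
        for comp in (ux, uy):
            med = ndi.generic_filter(comp, np.nanmedian, size=3, mode="nearest")
            resid = np.abs(comp - med)
            rmed = ndi.generic_filter(resid, np.nanmedian, size=3, mode="nearest")
            bad = resid > (2.0 * rmed + 0.1)
            ux[bad] = np.nan
            uy[bad] = np.nan
    # Gaussian-weighted smoothing / fill-in (normalized convolution)
    sig = smooth_sigma / grid_spacing
    mask = np.isfinite(ux) & np.isfinite(uy)
    if not mask.any():
        raise ValueError("no valid displacement estimates (featureless images?)")
    wsum = ndi.gaussian_filter(mask.astype(float), sig)
    with np.errstate(invalid="ignore"):
        ux_s = ndi.gaussian_filter(np.where(mask, ux, 0.0), sig) / wsum
        uy_s = ndi.gaussian_filter(np.where(mask, uy, 0.0), sig) / wsum
    ux_s[wsum < 1e-6] = 0.0
    uy_s[wsum < 1e-6] = 0.0
    return DisplacementField(x=xs, y=ys, t=t, ux=ux_s, uy=uy_s, quality=quality)


def compute_traction(
    displacements: DisplacementField,
    gel: GelSubstrate,
    lam: float = 0.0,
    pad_factor: int = 4,
) -> TractionMap:
    """FTTC inversion of a displacement field into a traction map.

    Zero-padded spectral inversion of the Boussinesq transfer tensor with
    optional zeroth-order Tikhonov regularization ``lam``; the uniform mode
    is set to zero (absolute substrate translation is unobservable after
    drift correction).
    """
    tx, ty = apply_inverse(
        displacements.ux,
        displacements.uy,
        displacements.spacing,
        gel.E,
        gel.nu,
        lam=lam,
        pad_factor=pad_factor,
    )
    return TractionMap(
        x=displacements.x, y=displacements.y, t=displacements.t, tx=tx, ty=ty
    )
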