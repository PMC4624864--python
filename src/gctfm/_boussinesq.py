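"""Spectral Boussinesq kernel for an elastic half-space surface.

The surface displacement response of a linear-elastic half-space (Young's
modulus E, Poisson ratio ν) to an in-plane surface traction t is a
convolution with the Boussinesq–Cerruti Green's tensor.  In Fourier space
(wavevector k = (kx, ky), k = |k|):

    u~(k) = G(k) t~(k),
    G(k) = 2 (1 + ν) / (E k³) [ (1-ν) k² + ν ky² ,  -ν kx ky
                                -ν kx ky          ,  (1-ν) k² + ν kx² ]

whose real-space counterpart is

    G(r) = (1 + ν) / (π E r³) [ (1-ν) r² + ν x² ,  ν x y
                                ν x y            ,  (1-ν) r² + ν y² ].

The k = 0 (uniform) mode has infinite compliance and is unobservable; it is
set to zero, so spectral solutions are the zero-mean representatives over
the padded domain.  Both the forward map (traction → displacement) and the
FTTC inverse (displacement → traction) are built from the same tensor.
"""

from __future__ import annotations

import numpy as np
from scipy import fft as spfft


def _wavevectors(n: int, d: float) -> np.ndarray:
    return 2.0 * np.pi * spfft.fftfreq(n, d)


def greens_tensor(ny: int, nx: int, spacing: float, E: float, nu: float):
    """Gxx, Gxy, Gyy on the (ny, nx) DFT wavevector grid; k=0 entries are 0."""
    if E <= 0:
        raise ValueError("Young's modulus must be positive")
    if not (0.0 <= nu < 0.5):
        raise ValueError("Poisson ratio must lie in [0, 0.5)")
    kx = _wavevectors(nx, spacing)[None, :]
    ky = _wavevectors(ny, spacing)[:, None]
    k = np.hypot(kx, ky)
    with np.errstate(divide="ignore", invalid="ignore"):
        pref = 2.0 * (1.0 + nu) / (E * k ** 3)
    pref[0, 0] = 0.0
    gxx = pref * ((1.0 - nu) * k ** 2 + nu * ky ** 2)
    gyy = pref * ((1.0 - nu) * k ** 2 + nu * kx ** 2)
    gxy = -pref * nu * kx * ky
    return gxx, gxy, gyy


def _pad(a: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    out = np.zeros(shape, dtype=a.dtype)
    out[: a.shape[0], : a.shape[1]] = a
    return out


def apply_forward(
    tx: np.ndarray,
    ty: np.ndarray,
    spacing: float,
    E: float,
    nu: float,
    pad_factor: int = 4,
) -> tuple[np.ndarray, np.ndarray]:
    """Displacement (μm) from traction (Pa) via the spectral Green's tensor.

    Inputs are zero-padded by ``pad_factor`` in each dimension to suppress
    wrap-around from the slowly decaying kernel, then cropped back.
    """
    ny, nx = tx.shape
    shape = (pad_factor * ny, pad_factor * nx)
    gxx, gxy, gyy = greens_tensor(shape[0], shape[1], spacing, E, nu)
    txf = spfft.fft2(_pad(tx, shape))
    tyf = spfft.fft2(_pad(ty, shape))
    ux = spfft.ifft2(gxx * txf + gxy * tyf).real
    uy = spfft.ifft2(gxy * txf + gyy * tyf).real
    return ux[:ny, :nx], uy[:ny, :nx]


def apply_inverse(
    ux: np.ndarray,
    uy: np.ndarray,
    spacing: float,
    E: float,
    nu: float,
    lam: float = 0.0,
    pad_factor: int = 4,
) -> tuple[np.ndarray, np.ndarray]:
    """FTTC: traction (Pa) from displacement (μm).

    Per wavevector the 2×2 tensor is inverted; with ``lam`` > 0 a
    zeroth-order Tikhonov term is used, t = (GᵀG + λ²I)⁻¹ Gᵀ u.  The
    uniform mode is zeroed.
    """
    if lam < 0:
        raise ValueError("regularization parameter must be non-negative")
    if not (np.all(np.isfinite(ux)) and np.all(np.isfinite(uy))):
        raise ValueError("displacement field contains non-finite values")
    ny, nx = ux.shape
    shape = (pad_factor * ny, pad_factor * nx)
    gxx, gxy, gyy = greens_tensor(shape[0], shape[1], spacing, E, nu)
    uxf = spfft.fft2(_pad(ux, shape))
    uyf = spfft.fft2(_pad(uy, shape))
    if lam == 0.0:
        det = gxx * gyy - gxy ** 2
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = 1.0 / det
        inv[0, 0] = 0.0
        inv[~np.isfinite(inv)] = 0.0
        txf = inv * (gyy * uxf - gxy * uyf)
        tyf = inv * (-gxy * uxf + gxx * uyf)
    else:
        # G is symmetric, so GᵀG = G².  Work with the 2x2 normal equations.
        axx = gxx * gxx + gxy * gxy + lam ** 2
        axy = gxy * (gxx + gyy)
        ayy = gyy * gyy + gxy * gxy + lam ** 2
        bxf = gxx * uxf + gxy * uyf
        byf = gxy * uxf + gyy * uyf
        det = axx * ayy - axy ** 2
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = 1.0 / det
        inv[~np.isfinite(inv)] = 0.0
        txf = inv * (ayy * bxf - axy * byf)
        tyf = inv * (-axy * bxf + axx * byf)
    txf[0, 0] = 0.0
    tyf[0, 0] = 0.0
    tx = spfft.ifft2(txf).real
    ty = spfft.ifft2(tyf).real
    return tx[:ny, :nx], ty[:ny, :nx]


def point_force_displacement(
    x: np.ndarray,
    y: np.ndarray,
    force: tuple[float, float],
    E: float,
    nu: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form surface displacement of a tangential point force.

    ``force`` in pN (= Pa·μm²), positions in μm, output in μm.  Singular at
    the origin; callers should evaluate away from it.
    """
    fx, fy = force
    r = np.hypot(x, y)
    with np.errstate(divide="ignore", invalid="ignore"):
        pref = (1.0 + nu) / (np.pi * E * r ** 3)
        ux = pref * (((1.0 - nu) * r ** 2 + nu * x ** 2) * fx + nu * x * y * fy)
        uy = pref * (nu * x * y * fx + ((1.0 - nu) * r ** 2 + nu * y ** 2) * fy)
    return ux, uy
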