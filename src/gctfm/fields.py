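"""Grid-based vector-field containers shared by all pipeline stages.

Conventions
-----------
Fields live on a regular 2D grid of nodes.  Arrays are indexed ``[iy, ix]``
and the node coordinates are carried explicitly as 1D ``x`` (length nx) and
``y`` (length ny) vectors in micrometres.  y increases with row index
throughout the package (no image-style flip anywhere).

Units: lengths and displacements in μm, stresses in Pa, forces in nN
(1 Pa·μm² = 1 pN = 1e-3 nN).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: conversion factor from Pa·μm² to nN
PA_UM2_TO_NN = 1e-3


def _check_grid(x: np.ndarray, y: np.ndarray, *components: np.ndarray) -> None:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.ndim != 1 or y.ndim != 1 or x.size < 2 or y.size < 2:
        raise ValueError("grid axes must be 1D with at least two nodes")
    dx = np.diff(x)
    dy = np.diff(y)
    if not (np.allclose(dx, dx[0]) and np.allclose(dy, dy[0])):
        raise ValueError("grid must be regular")
    if not np.isclose(dx[0], dy[0]):
        raise ValueError("grid spacing must be isotropic")
    if dx[0] <= 0:
        raise ValueError("grid spacing must be positive")
    for c in components:
        if np.asarray(c).shape != (y.size, x.size):
            raise ValueError("component shape must be (ny, nx)")


@dataclass
class _VectorField2D:
    x: np.ndarray
    y: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, float)
        self.y = np.asarray(self.y, float)

    @property
    def spacing(self) -> float:
        return float(self.x[1] - self.x[0])

    @property
    def shape(self) -> tuple[int, int]:
        return (self.y.size, self.x.size)

    @property
    def cell_area(self) -> float:
        return self.spacing ** 2

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray]:
        return np.meshgrid(self.x, self.y)


@dataclass
class TractionMap(_VectorField2D):
    """Traction stress vectors (Pa) on a regular grid at one time point."""

    tx: np.ndarray = field(default=None)  # type: ignore[assignment]
    ty: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        super().__post_init__()
        self.tx = np.asarray(self.tx, float)
        self.ty = np.asarray(self.ty, float)
        _check_grid(self.x, self.y, self.tx, self.ty)

    def magnitude(self) -> np.ndarray:
        return np.hypot(self.tx, self.ty)

    def congruent(self, other: "TractionMap") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.x, other.x)
            and np.allclose(self.y, other.y)
        )


@dataclass
class DisplacementField(_VectorField2D):
    """Substrate displacement vectors (μm) on a regular grid.

    ``quality`` holds the cross-correlation peak height per node when the
    field was measured from images; it is None for forward-modelled fields.
    """

    ux: np.ndarray = field(default=None)  # type: ignore[assignment]
    uy: np.ndarray = field(default=None)  # type: ignore[assignment]
    quality: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        super().__post_init__()
        self.ux = np.asarray(self.ux, float)
        self.uy = np.asarray(self.uy, float)
        _check_grid(self.x, self.y, self.ux, self.uy)

    def magnitude(self) -> np.ndarray:
        return np.hypot(self.ux, self.uy)


def net_force(tm: TractionMap) -> np.ndarray:
    """Vector sum of the traction field times cell area, in nN.

    The traction is the stress the cell exerts on the substrate; the axon
    tension is equal and opposite to this net traction force.
    """
    a = tm.cell_area
    fx = np.nansum(tm.tx) * a * PA_UM2_TO_NN
    fy = np.nansum(tm.ty) * a * PA_UM2_TO_NN
    return np.array([fx, fy])


def make_grid(field_size: tuple[float, float], spacing: float) -> tuple[np.ndarray, np.ndarray]:
    """Node coordinates covering ``field_size`` = (Lx, Ly) μm at ``spacing`` μm."""
    lx, ly = field_size
    nx = int(round(lx / spacing)) + 1
    ny = int(round(ly / spacing)) + 1
    return spacing * np.arange(nx), spacing * np.arange(ny)
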