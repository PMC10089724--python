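"""Gridded velocity and pressure field containers.

The containers mirror what planar PIV software exports: a time-ordered stack
of 2-D velocity grids on a fixed rectangular mesh, with a boolean mask marking
cells occupied by the body or outside the field of view.  All quantities are
SI (metres, seconds, pascals); the coordinate convention is x rightward,
y upward, origin at the lower-left grid node.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .errors import DataError


@dataclass
class VelocityFieldSeries:
    """Time-ordered 2-D gridded velocity frames.

    Attributes
    ----------
    u, v : ndarray, shape (nt, ny, nx)
        Velocity components in m/s.  Masked cells hold NaN.
    mask : ndarray of bool, shape (ny, nx)
        True where the cell is body / out of view (no fluid data).
    x, y : ndarray
        Node coordinates (m), uniformly spaced.
    dt : float
        Frame interval (s).
    t0 : float
        Time of the first frame (s).
    meta : dict
        Free-form sequence metadata (density, mouth trajectory, ...).
    """

    u: np.ndarray
    v: np.ndarray
    mask: np.ndarray
    x: np.ndarray
    y: np.ndarray
    dt: float
    t0: float = 0.0
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, float)
        self.v = np.asarray(self.v, float)
        self.mask = np.asarray(self.mask, bool)
        self.x = np.asarray(self.x, float)
        self.y = np.asarray(self.y, float)
        self.validate()

    # -- basic geometry --------------------------------------------------
    @property
    def nt(self) -> int:
        return self.u.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.u.shape[1:]

    @property
    def dx(self) -> float:
        return float(self.x[1] - self.x[0])

    @property
    def dy(self) -> float:
        return float(self.y[1] - self.y[0])

    @property
    def t(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.nt)

    def validate(self) -> None:
        if self.u.ndim != 3 or self.u.shape != self.v.shape:
            raise DataError("u and v must be (nt, ny, nx) arrays of equal shape")
        ny, nx = self.u.shape[1:]
        if self.mask.shape != (ny, nx):
            raise DataError(f"mask shape {self.mask.shape} != grid shape {(ny, nx)}")
        if len(self.x) != nx or len(self.y) != ny:
            raise DataError("axis lengths inconsistent with grid shape")
        if self.dt <= 0:
            raise DataError("frame interval dt must be positive")
        for ax in (self.x, self.y):
            d = np.diff(ax)
            if not np.allclose(d, d[0], rtol=1e-6) or d[0] <= 0:
                raise DataError("grid axes must be uniform and increasing")
        # masked cells carry no velocity
        self.u[:, self.mask] = np.nan
        self.v[:, self.mask] = np.nan

    def speed(self) -> np.ndarray:
        """|u| per frame, NaN on masked cells."""
        return np.hypot(self.u, self.v)


@dataclass
class PressureFieldSeries:
    """Gauge-pressure grids aligned to a :class:`VelocityFieldSeries`.

    ``reference`` documents the zero-pressure convention (which cells were
    anchored to zero gauge pressure).  Masked / unreachable cells hold NaN.
    """

    p: np.ndarray
    mask: np.ndarray
    x: np.ndarray
    y: np.ndarray
    dt: float
    t0: float = 0.0
    reference: str = "far-field boundary cells"
    reference_cells: np.ndarray | None = None  # (k, 2) int row/col indices
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, float)
        self.mask = np.asarray(self.mask, bool)
        self.p[:, self.mask] = np.nan

    @property
    def nt(self) -> int:
        return self.p.shape[0]

    @property
    def t(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.nt)


@dataclass
class PhysicalParams:
    """Fluid properties and inversion geometry.

    density : kg/m^3, defaults to seawater.
    nu : kinematic viscosity (m^2/s); viscous terms are neglected when 0.
    geometry : 'planar' or 'axisymmetric'.  In axisymmetric mode the PIV
        plane is taken as the symmetry plane and cells are volume-weighted
        by their distance from the mouth axis.
    axis_point, axis_dir : a point on the mouth axis and its unit direction
        (grid coordinates); only used in axisymmetric mode.
    """

    density: float = 1025.0
    nu: float = 0.0
    geometry: str = "axisymmetric"
    axis_point: tuple[float, float] = (0.0, 0.0)
    axis_dir: tuple[float, float] = (1.0, 0.0)

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise DataError("density must be positive")
        if self.nu < 0:
            raise DataError("kinematic viscosity must be non-negative")
        if self.geometry not in ("planar", "axisymmetric"):
            raise DataError(f"unknown geometry {self.geometry!r}")
        n = float(np.hypot(*self.axis_dir))
        if n == 0:
            raise DataError("axis_dir must be a non-zero vector")
        self.axis_dir = (self.axis_dir[0] / n, self.axis_dir[1] / n)

    def axis_distance(self, X: np.ndarray, Y: np.ndarray) -> np.ndarray:
        """Perpendicular distance of grid points from the mouth axis."""
        px, py = self.axis_point
        dx, dy = self.axis_dir
        return np.abs(-(X - px) * dy + (Y - py) * dx)
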