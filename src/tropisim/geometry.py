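"""Median-line geometry of a growing plant organ.

The organ is described by its median line, parameterized by the curvilinear
abscissa ``s`` running from the base (``s = 0``) to the apex (``s = L``).
``A(s)`` is the local orientation with respect to the upward vertical
(radians, positive toward the light half-plane) and ``C(s)`` is the local
curvature, the spatial rate of change of ``A``::

    C(s) = dA/ds        A(s) = A(0) + integral_0^s C(l) dl

This module converts between the angle, curvature and planar (x, y)
descriptions of the shape.  All angles are radians internally; degree
conversion happens only at I/O boundaries (see :mod:`tropisim.io_`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.typing import ArrayLike, NDArray
from scipy.integrate import cumulative_simpson, cumulative_trapezoid


class GridError(ValueError):
    """Raised for a non-monotone or otherwise invalid arc-length grid."""


class ResolutionError(ValueError):
    """Raised when a grid is too coarse for the requested operation."""


class DegenerateSegmentError(ValueError):
    """Raised when consecutive midline points coincide."""


def _validate_grid(s_grid: NDArray[np.floating]) -> None:
    if s_grid.ndim != 1 or s_grid.size < 2:
        raise GridError("arc-length grid must be 1-D with at least two nodes")
    if not np.all(np.diff(s_grid) > 0):
        raise GridError("arc-length grid must be strictly increasing")


def curvature_to_angles(
    curvature_profile: ArrayLike,
    base_angle: float,
    s_grid: ArrayLike,
) -> NDArray[np.float64]:
    """Integrate a curvature profile into an angle profile.

    ``A(s) = base_angle + integral of C from 0 to s``, by cumulative Simpson
    quadrature (trapezoid on two-node grids).
    """
    s = np.asarray(s_grid, dtype=float)
    c = np.asarray(curvature_profile, dtype=float)
    _validate_grid(s)
    if not np.isfinite(base_angle):
        raise ValueError("base_angle must be finite")
    if c.shape != s.shape:
        raise GridError("curvature profile and grid must have matching shapes")
    if s.size < 3:
        return base_angle + cumulative_trapezoid(c, s, initial=0.0)
    return base_angle + cumulative_simpson(c, x=s, initial=0.0)


def angles_to_curvature(
    angle_profile: ArrayLike,
    s_grid: ArrayLike,
) -> NDArray[np.float64]:
    """Differentiate an angle profile into a curvature profile.

    Second-order central differences in the interior, one-sided at the ends
    (``numpy.gradient`` with an explicit coordinate array).
    """
    s = np.asarray(s_grid, dtype=float)
    a = np.asarray(angle_profile, dtype=float)
    _validate_grid(s)
    if s.size < 3:
        raise ResolutionError("need at least 3 grid nodes to differentiate")
    if a.shape != s.shape:
        raise GridError("angle profile and grid must have matching shapes")
    return np.gradient(a, s, edge_order=2)


@dataclass
class OrganShape:
    """Discretized median line: arc-length grid, angle field, curvature field.

    Attributes
    ----------
    s_grid:
        Strictly increasing arc-length positions from 0 to ``length``.
    angle:
        Local orientation ``A(s)`` w.r.t. the upward vertical (rad).
    curvature:
        Local curvature ``C(s)`` (1/length).  Must be consistent with the
        angle field through ``C = dA/ds`` within discretization tolerance.
    """

    s_grid: NDArray[np.float64]
    angle: NDArray[np.float64]
    curvature: NDArray[np.float64]
    length: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.s_grid = np.asarray(self.s_grid, dtype=float)
        self.angle = np.asarray(self.angle, dtype=float)
        self.curvature = np.asarray(self.curvature, dtype=float)
        _validate_grid(self.s_grid)
        if self.s_grid[0] != 0.0:
            raise GridError("arc-length grid must start at 0")
        if self.length is None:
            self.length = float(self.s_grid[-1])
        elif not np.isclose(self.s_grid[-1], self.length, rtol=1e-9, atol=0.0):
            raise GridError("grid endpoint must equal the organ length")
        if self.angle.shape != self.s_grid.shape:
            raise GridError("angle field must have one value per grid node")
        if self.curvature.shape != self.s_grid.shape:
            raise GridError("curvature field must have one value per grid node")

    @classmethod
    def from_curvature(
        cls,
        curvature: ArrayLike,
        base_angle: float,
        s_grid: ArrayLike,
    ) -> "OrganShape":
        s = np.asarray(s_grid, dtype=float)
        c = np.asarray(curvature, dtype=float)
        return cls(s, curvature_to_angles(c, base_angle, s), c)

    @classmethod
    def from_angles(cls, angle: ArrayLike, s_grid: ArrayLike) -> "OrganShape":
        s = np.asarray(s_grid, dtype=float)
        a = np.asarray(angle, dtype=float)
        return cls(s, a, angles_to_curvature(a, s))

    @classmethod
    def straight(cls, angle: float, length: float, n_nodes: int = 201) -> "OrganShape":
        """A straight organ tilted at a uniform angle."""
        s = np.linspace(0.0, length, n_nodes)
        return cls(s, np.full(n_nodes, float(angle)), np.zeros(n_nodes))

    def consistency_error(self) -> float:
        """Sup-norm mismatch between the angle field and the integral of C."""
        rebuilt = curvature_to_angles(self.curvature, float(self.angle[0]), self.s_grid)
        return float(np.max(np.abs(rebuilt - self.angle)))

    def tip_angle(self) -> float:
        return float(self.angle[-1])


def midline_xy(shape: OrganShape) -> NDArray[np.float64]:
    """Planar coordinates of the median line.

    ``x(s) = integral_0^s sin A dl``, ``y(s) = integral_0^s cos A dl`` — the
    base sits at the origin and a vertical organ (A = 0) points along +y.
    Returns an (n, 2) array of (x, y) per grid node.
    """
    x = cumulative_trapezoid(np.sin(shape.angle), shape.s_grid, initial=0.0)
    y = cumulative_trapezoid(np.cos(shape.angle), shape.s_grid, initial=0.0)
    return np.column_stack([x, y])


def xy_to_shape(point_sequence: ArrayLike, n_nodes: int | None = None) -> OrganShape:
    """Reconstruct an :class:`OrganShape` from ordered base-to-apex points.

    The polyline is resampled to uniform arc length, the angle field is taken
    from the local tangent direction w.r.t. the vertical, and curvature by
    finite differences of the angle field.
    """
    pts = np.asarray(point_sequence, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 ordered (x, y) points")
    seg = np.diff(pts, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    if np.any(seg_len == 0.0):
        raise DegenerateSegmentError("duplicate consecutive midline points")
    arclen = np.concatenate([[0.0], np.cumsum(seg_len)])
    if n_nodes is None:
        n_nodes = pts.shape[0]
    s = np.linspace(0.0, arclen[-1], n_nodes)
    x = np.interp(s, arclen, pts[:, 0])
    y = np.interp(s, arclen, pts[:, 1])
    dx = np.gradient(x, s, edge_order=2)
    dy = np.gradient(y, s, edge_order=2)
    angle = np.unwrap(np.arctan2(dx, dy))
    return OrganShape.from_angles(angle, s)
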