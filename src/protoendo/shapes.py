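"""Axisymmetric membrane contours and surface-of-revolution geometry.

A vesicle surface is represented by its generating polyline in the (r, z)
half-plane, ordered pole to pole with r = 0 exactly at both end markers.
Rotating the polyline about the z axis yields the closed surface; area,
enclosed volume and the two principal curvatures (meridional and
azimuthal) are obtained by quadrature of the polyline.

The low-level quadrature functions accept batched marker arrays of shape
(..., N, 2) and are written with complex-analytic operations only
(sqrt/arcsin, no abs or arctan2) so that energy gradients can be taken by
complex-step differentiation to machine precision.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from shapely.geometry import LineString

from .errors import InvalidShapeError

__all__ = [
    "AxisymShape",
    "compute_geometry",
    "sphere_shape",
    "spheroid_shape",
    "cap_inverted_sphere",
    "resample",
]


# ---------------------------------------------------------------------------
# batched, complex-safe quadrature primitives
# ---------------------------------------------------------------------------

def segment_lengths(x):
    """Chord lengths of the polyline; x has shape (..., N, 2)."""
    d = x[..., 1:, :] - x[..., :-1, :]
    return np.sqrt(d[..., 0] ** 2 + d[..., 1] ** 2)


def surface_area(x):
    """Area of the surface of revolution, Sum 2*pi*r_mid*L per segment."""
    r = x[..., 0]
    L = segment_lengths(x)
    r_mid = 0.5 * (r[..., 1:] + r[..., :-1])
    return 2.0 * np.pi * np.sum(r_mid * L, axis=-1)


def enclosed_volume(x):
    """Signed enclosed volume, Sum pi*r_mid^2*dz per segment.

    Positive for a contour traversed from the low-z pole to the high-z
    pole; callers normalize orientation so this is > 0 for valid shapes.
    """
    r = x[..., 0]
    z = x[..., 1]
    dz = z[..., 1:] - z[..., :-1]
    r_mid = 0.5 * (r[..., 1:] + r[..., :-1])
    return np.pi * np.sum(r_mid ** 2 * dz, axis=-1)


def principal_curvatures(x):
    """Per-marker meridional and azimuthal curvatures (c_m, c_phi).

    Interior markers use the turning angle between adjacent chords and
    sin(psi)/r; pole markers use the osculating-circle formula through the
    pole, for which both principal curvatures coincide.  Returns two
    arrays of shape (..., N).  Sign convention: positive for a convex
    (sphere-like) surface, negative on the wall of an inward cavity.
    """
    r = x[..., 0]
    z = x[..., 1]
    d = x[..., 1:, :] - x[..., :-1, :]
    L = segment_lengths(x)
    t = d / L[..., None]

    # interior: turning angle between successive unit tangents
    cross = t[..., :-1, 0] * t[..., 1:, 1] - t[..., :-1, 1] * t[..., 1:, 0]
    theta = np.arcsin(cross)
    c_m_int = 2.0 * theta / (L[..., :-1] + L[..., 1:])

    # interior azimuthal: z-component of the node tangent / r
    tn = d[..., :-1, :] + d[..., 1:, :]
    tn_norm = np.sqrt(tn[..., 0] ** 2 + tn[..., 1] ** 2)
    sin_psi = tn[..., 1] / tn_norm
    c_phi_int = sin_psi / r[..., 1:-1]

    # poles: circle through the pole with tangent normal to the axis
    dz0 = z[..., 1] - z[..., 0]
    c_pole0 = 2.0 * dz0 / (r[..., 1] ** 2 + dz0 ** 2)
    dz1 = z[..., -1] - z[..., -2]
    c_pole1 = 2.0 * dz1 / (r[..., -2] ** 2 + dz1 ** 2)

    shape = x.shape[:-2] + (x.shape[-2],)
    c_m = np.empty(shape, dtype=x.dtype)
    c_phi = np.empty(shape, dtype=x.dtype)
    c_m[..., 1:-1] = c_m_int
    c_phi[..., 1:-1] = c_phi_int
    c_m[..., 0] = c_pole0
    c_phi[..., 0] = c_pole0
    c_m[..., -1] = c_pole1
    c_phi[..., -1] = c_pole1
    return c_m, c_phi


def node_areas(x):
    """Quadrature weights per marker, 2*pi*r_i*(L_{i-1}+L_i)/2.

    Pole markers get zero weight (r = 0); the interior weights sum exactly
    to the total surface area.
    """
    r = x[..., 0]
    L = segment_lengths(x)
    a = np.zeros(x.shape[:-2] + (x.shape[-2],), dtype=x.dtype)
    a[..., 1:-1] = np.pi * r[..., 1:-1] * (L[..., :-1] + L[..., 1:])
    return a


# ---------------------------------------------------------------------------
# the public contour type
# ---------------------------------------------------------------------------

@dataclass
class AxisymShape:
    """Discretized axisymmetric membrane contour.

    markers : (N, 2) array of (r, z) pairs in um, ordered pole to pole,
    with r = 0 at both end markers and r > 0 in between.
    """

    markers: np.ndarray = field()

    def __post_init__(self):
        m = np.asarray(self.markers, dtype=float)
        if m.ndim != 2 or m.shape[1] != 2:
            raise InvalidShapeError("markers must be an (N, 2) array of (r, z)")
        if m.shape[0] < 4:
            raise InvalidShapeError(
                f"need at least 4 markers, got {m.shape[0]}"
            )
        if not (abs(m[0, 0]) < 1e-9 and abs(m[-1, 0]) < 1e-9):
            raise InvalidShapeError("end markers must lie on the axis (r = 0)")
        m[0, 0] = 0.0
        m[-1, 0] = 0.0
        if np.any(m[1:-1, 0] <= 0.0):
            raise InvalidShapeError("interior markers must have r > 0")
        if enclosed_volume(m) < 0.0:
            m = m[::-1].copy()
        if enclosed_volume(m) <= 0.0:
            raise InvalidShapeError("enclosed volume must be positive")
        if not LineString(m).is_simple:
            raise InvalidShapeError("contour is self-intersecting")
        self.markers = m

    # -- derived geometry ---------------------------------------------------
    @property
    def n_markers(self) -> int:
        return self.markers.shape[0]

    @property
    def area(self) -> float:
        """Surface area in um^2."""
        return float(surface_area(self.markers))

    @property
    def volume(self) -> float:
        """Enclosed volume in um^3."""
        return float(enclosed_volume(self.markers))

    @property
    def mean_curvature(self) -> np.ndarray:
        """Per-marker mean curvature H = (c_m + c_phi)/2 in um^-1."""
        c_m, c_phi = principal_curvatures(self.markers)
        return 0.5 * (c_m + c_phi)

    @property
    def equivalent_radius(self) -> float:
        """Radius of the sphere with the same volume, um."""
        return float((3.0 * self.volume / (4.0 * np.pi)) ** (1.0 / 3.0))

    def arclengths(self) -> np.ndarray:
        """Cumulative arclength at each marker, starting at 0."""
        L = segment_lengths(self.markers)
        return np.concatenate([[0.0], np.cumsum(L)])


def compute_geometry(shape: AxisymShape):
    """Return (area um^2, volume um^3, per-marker mean curvature um^-1)."""
    return shape.area, shape.volume, shape.mean_curvature


# ---------------------------------------------------------------------------
# constructors
# ---------------------------------------------------------------------------

def _polar_angles(n: int) -> np.ndarray:
    return np.linspace(0.0, np.pi, n)


def sphere_shape(radius: float = 0.5, n_markers: int = 64) -> AxisymShape:
    """Sphere of the given radius (um), markers equispaced in polar angle."""
    u = _polar_angles(n_markers)
    return AxisymShape(np.column_stack([radius * np.sin(u),
                                        -radius * np.cos(u)]))


def spheroid_shape(polar_semi_axis: float, equatorial_semi_axis: float,
                   n_markers: int = 128) -> AxisymShape:
    """Spheroid with symmetry axis z: prolate if polar > equatorial."""
    u = _polar_angles(n_markers)
    return AxisymShape(np.column_stack([
        equatorial_semi_axis * np.sin(u),
        -polar_semi_axis * np.cos(u),
    ]))


def cap_inverted_sphere(radius: float = 1.0, cap_depth: float = 0.6,
                        n_markers: int = 128) -> AxisymShape:
    """Sphere with a spherical cap at the low-z pole reflected inward.

    cap_depth is the cap height as a fraction of the radius; the inverted
    cap forms an inner cavity opening through a rim crease — the analytic
    stomatocyte fixture used to exercise cavity detection.
    """
    if not 0.0 < cap_depth < 1.0:
        raise ValueError("cap_depth must be in (0, 1)")
    u = _polar_angles(n_markers)
    r = radius * np.sin(u)
    z = -radius * np.cos(u)
    z_plane = -radius + cap_depth * radius
    in_cap = z < z_plane
    z[in_cap] = 2.0 * z_plane - z[in_cap]
    return AxisymShape(np.column_stack([r, z]))


def resample(shape: AxisymShape, n_markers: int) -> AxisymShape:
    """Redistribute markers uniformly in arclength via cubic splines."""
    if n_markers < 4:
        raise InvalidShapeError("need at least 4 markers")
    s = shape.arclengths()
    sr = CubicSpline(s, shape.markers[:, 0])
    sz = CubicSpline(s, shape.markers[:, 1])
    s_new = np.linspace(0.0, s[-1], n_markers)
    r_new = np.clip(sr(s_new), 0.0, None)
    z_new = sz(s_new)
    r_new[0] = 0.0
    r_new[-1] = 0.0
    # splines can graze zero near the poles; nudge interior points off axis
    tiny = 1e-9 * max(s[-1], 1.0)
    r_new[1:-1] = np.maximum(r_new[1:-1], tiny)
    return AxisymShape(np.column_stack([r_new, z_new]))
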