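"""Closed-form 3D geometry used throughout the virtual-microtomy pipeline.

All coordinates are in micrometres, right-handed. Ellipsoids are represented
by a centre, semi-axes ``(a, b, c)`` and a rotation matrix ``R`` mapping local
to world coordinates; the associated quadric is ``(x-c)^T M (x-c) = 1`` with
``M = R diag(1/a^2, 1/b^2, 1/c^2) R^T``. Planes are parameterised by a unit
normal ``n``, an origin point and an in-plane orthonormal basis ``(e1, e2)``.
"""

from __future__ import annotations

import numpy as np
from numpy.polynomial.legendre import leggauss

__all__ = [
    "random_unit_vectors",
    "random_rotation_matrix",
    "plane_basis",
    "ellipsoid_quadric",
    "plane_ellipsoid_ellipse",
    "sphere_plane_disc",
    "line_quadric_roots",
    "ellipsoid_surface_area",
    "cap_fraction_curve",
    "solve_cap_angle",
    "sphere_volume",
    "sphere_surface",
    "radius_from_volume",
]


def sphere_volume(r):
    return (4.0 / 3.0) * np.pi * np.asarray(r) ** 3


def sphere_surface(r):
    return 4.0 * np.pi * np.asarray(r) ** 2


def radius_from_volume(v):
    return (3.0 * np.asarray(v) / (4.0 * np.pi)) ** (1.0 / 3.0)


def random_unit_vectors(rng: np.random.Generator, n: int | None = None) -> np.ndarray:
    """Isotropic unit vectors (uniform on the sphere)."""
    size = (n, 3) if n is not None else 3
    v = rng.normal(size=size)
    norm = np.linalg.norm(v, axis=-1, keepdims=True)
    return v / norm


def random_rotation_matrix(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation (Haar measure) via quaternions."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def plane_basis(normal: np.ndarray, rng: np.random.Generator | None = None):
    """Orthonormal in-plane basis (e1, e2) for a unit normal.

    If ``rng`` is given, the basis is additionally rotated by a uniform random
    angle within the plane (grid/frame orientation randomisation).
    """
    n = np.asarray(normal, dtype=float)
    n = n / np.linalg.norm(n)
    helper = np.array([1.0, 0.0, 0.0]) if abs(n[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(n, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    if rng is not None:
        phi = rng.uniform(0.0, 2.0 * np.pi)
        e1, e2 = np.cos(phi) * e1 + np.sin(phi) * e2, -np.sin(phi) * e1 + np.cos(phi) * e2
    return e1, e2


def ellipsoid_quadric(axes: np.ndarray, rotation: np.ndarray) -> np.ndarray:
    """Quadric matrix M with (x-c)^T M (x-c) = 1 on the surface."""
    d = 1.0 / np.asarray(axes, dtype=float) ** 2
    return rotation @ np.diag(d) @ rotation.T


def plane_ellipsoid_ellipse(center, M, origin, e1, e2):
    """Intersection ellipse of a plane with an ellipsoid.

    The plane is ``{origin + u e1 + v e2}``. Returns ``None`` if the plane
    misses the ellipsoid (tangency counts as a miss), else
    ``(center2d, semi_axes2d, angle)`` in plane coordinates, with ``angle`` the
    orientation of the major axis relative to ``e1``.
    """
    d = np.asarray(origin, dtype=float) - np.asarray(center, dtype=float)
    E = np.stack([e1, e2], axis=1)  # 3x2
    Q = E.T @ M @ E
    b = E.T @ (M @ d)
    c0 = float(d @ M @ d) - 1.0
    try:
        u0 = np.linalg.solve(Q, -b)
    except np.linalg.LinAlgError:  # pragma: no cover - degenerate quadric
        return None
    k = -(c0 + b @ u0)  # = -f(u0); ellipse exists iff k > 0
    if k <= 0.0:
        return None
    evals, evecs = np.linalg.eigh(Q)
    semi = np.sqrt(k / evals)  # descending semi-axes come from ascending evals
    order = np.argsort(semi)[::-1]
    semi = semi[order]
    major = evecs[:, order[0]]
    angle = float(np.arctan2(major[1], major[0]))
    return u0, semi, angle


def sphere_plane_disc(center, radius, origin, normal, e1, e2):
    """Disc of a sphere cut by a plane, or None. Tangency counts as a miss."""
    d = float((np.asarray(center) - np.asarray(origin)) @ np.asarray(normal))
    r2 = radius * radius - d * d
    if r2 <= 0.0:
        return None
    rel = np.asarray(center) - np.asarray(origin)
    return np.array([rel @ e1, rel @ e2]), float(np.sqrt(r2))


def line_quadric_roots(p0, w, center, M):
    """Parameters s of the intersections of line p0 + s*w with an ellipsoid.

    Returns (s_minus, s_plus) or None for no transversal crossing.
    """
    d = np.asarray(p0, dtype=float) - np.asarray(center, dtype=float)
    A = float(w @ M @ w)
    B = float(w @ M @ d)
    C = float(d @ M @ d) - 1.0
    disc = B * B - A * C
    if disc <= 0.0:
        return None
    sq = np.sqrt(disc)
    return (-B - sq) / A, (-B + sq) / A


# -- ellipsoid surface quadrature -------------------------------------------
# Gauss-Legendre product rule on the standard parametrisation
#   r(t, p) = (a sin t cos p, b sin t sin p, c cos t)
# with |r_t x r_p| = sin t * sqrt(c^2 sin^2 t (b^2 cos^2 p + a^2 sin^2 p)
#                                 + a^2 b^2 cos^2 t).

_GL_N = 96
_GL_X, _GL_W = leggauss(_GL_N)


def _area_element(axes, theta, phi):
    a, b, c = axes
    st, ct = np.sin(theta), np.cos(theta)
    return st * np.sqrt(
        c * c * st * st * (b * b * np.cos(phi) ** 2 + a * a * np.sin(phi) ** 2)
        + a * a * b * b * ct * ct
    )


def _band_area(axes, theta_lo, theta_hi):
    """Surface area of the parameter band theta in [lo, hi] (full phi circle)."""
    t = 0.5 * (theta_hi - theta_lo) * _GL_X + 0.5 * (theta_hi + theta_lo)
    wt = 0.5 * (theta_hi - theta_lo) * _GL_W
    p = np.pi * (_GL_X + 1.0)
    wp = np.pi * _GL_W
    T, P = np.meshgrid(t, p, indexing="ij")
    el = _area_element(axes, T, P)
    return float(wt @ el @ wp)


from functools import lru_cache


@lru_cache(maxsize=512)
def _surface_area_cached(key: tuple) -> float:
    return _band_area(np.array(key), 0.0, np.pi)


def ellipsoid_surface_area(axes) -> float:
    """Ellipsoid surface area by high-order quadrature (~1e-12 relative).

    Results are cached on the (rounded) semi-axes; scale-family shapes reuse
    one quadrature via ``S(s * axes) = s^2 S(axes)``.
    """
    axes = np.asarray(axes, dtype=float)
    s = float(axes[1])
    key = tuple(np.round(axes / s, 9))
    return s * s * _surface_area_cached(key)


def cap_fraction_curve(axes, theta):
    """Fraction of ellipsoid surface in the parameter cap {t <= theta}.

    The cap is defined in parameter space around the local +z axis; for a
    sphere this is the geodesic spherical cap with fraction (1 - cos theta)/2.
    """
    total = ellipsoid_surface_area(axes)
    return _band_area(axes, 0.0, theta) / total


@lru_cache(maxsize=512)
def _cap_angle_cached(key: tuple, fraction: float, tol: float) -> float:
    from scipy.optimize import brentq

    axes = np.array(key)
    total = ellipsoid_surface_area(axes)
    f = lambda th: _band_area(axes, 0.0, th) / total - fraction
    return float(brentq(f, 1e-9, np.pi - 1e-9, xtol=tol))


def solve_cap_angle(axes, fraction: float, tol: float = 1e-12) -> float:
    """Parameter cap angle whose surface fraction equals ``fraction``.

    Scale-invariant in the semi-axes, so results are cached on the
    normalised shape.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("cap fraction must be in (0, 1)")
    axes = np.asarray(axes, dtype=float)
    key = tuple(np.round(axes / float(axes[1]), 9))
    return _cap_angle_cached(key, float(fraction), float(tol))
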