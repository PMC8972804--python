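"""Pure geometric kernels used by scoring and calibration.

Distances are in ångström, all angular quantities in degrees.  Dihedral
angles follow the IUPAC sign convention (signed torsion in (-180, 180]).
Angular means and spreads are computed with circular statistics so that
distributions straddling the ±180° wrap point are handled correctly.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "distance",
    "angle",
    "dihedral",
    "angular_difference",
    "circular_mean_sd",
    "GeometryError",
]

_DEGENERACY_TOL = 1e-6


class GeometryError(ValueError):
    """Raised for degenerate or non-finite geometric input."""


def _as_vec(p) -> np.ndarray:
    v = np.asarray(p, dtype=float)
    if v.shape != (3,):
        raise GeometryError(f"expected a 3-vector, got shape {v.shape}")
    if not np.all(np.isfinite(v)):
        raise GeometryError(f"non-finite coordinates: {v}")
    return v


def distance(p, q) -> float:
    """Euclidean distance |p - q| in Å."""
    return float(np.linalg.norm(_as_vec(p) - _as_vec(q)))


def angle(a, vertex, c) -> float:
    """Included angle a–vertex–c in degrees, in [0, 180]."""
    u = _as_vec(a) - _as_vec(vertex)
    w = _as_vec(c) - _as_vec(vertex)
    nu = np.linalg.norm(u)
    nw = np.linalg.norm(w)
    if nu < _DEGENERACY_TOL or nw < _DEGENERACY_TOL:
        raise GeometryError("degenerate angle: zero-length arm")
    cosang = np.clip(np.dot(u, w) / (nu * nw), -1.0, 1.0)
    return float(math.degrees(math.acos(cosang)))


def dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion angle about p2–p3 in degrees, in (-180, 180].

    ``dihedral(p4, p3, p2, p1) == dihedral(p1, p2, p3, p4)`` and a mirror
    image negates the value.
    """
    b1 = _as_vec(p2) - _as_vec(p1)
    b2 = _as_vec(p3) - _as_vec(p2)
    b3 = _as_vec(p4) - _as_vec(p3)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    if nb2 < _DEGENERACY_TOL:
        raise GeometryError("degenerate dihedral: coincident central points")
    if np.linalg.norm(n1) < _DEGENERACY_TOL or np.linalg.norm(n2) < _DEGENERACY_TOL:
        raise GeometryError("degenerate dihedral: collinear triple")
    x = np.dot(n1, n2)
    y = np.dot(np.cross(n1, n2), b2) / nb2
    ang = math.degrees(math.atan2(y, x))
    # map -180 exactly to +180 so the range is (-180, 180]
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def angular_difference(x: float, y: float) -> float:
    """Smallest absolute difference between two angles, in [0, 180] degrees."""
    d = math.fmod(x - y, 360.0)
    if d < -180.0:
        d += 360.0
    elif d > 180.0:
        d -= 360.0
    return abs(d)


def circular_mean_sd(values: Iterable[float] | Sequence[float]) -> tuple[float, float]:
    """Circular mean direction and circular standard deviation, in degrees.

    The spread is the usual ``sqrt(-2 ln R)`` circular SD, which converges
    to the linear SD for tightly clustered samples.  Requires at least two
    values; an (almost) uniform sample, whose mean direction is undefined,
    raises :class:`GeometryError`.
    """
    vals = np.asarray(list(values), dtype=float)
    if vals.size < 2:
        raise GeometryError("circular statistics need at least 2 values")
    rad = np.radians(vals)
    z = np.exp(1j * rad).mean()
    r = abs(z)
    if r < 1e-9:
        raise GeometryError("mean direction undefined: resultant length ~ 0")
    mean = math.degrees(math.atan2(z.imag, z.real))
    if mean <= -180.0:
        mean += 360.0
    sd = math.degrees(math.sqrt(max(0.0, -2.0 * math.log(r))))
    return float(mean), float(sd)
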