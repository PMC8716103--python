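"""Rigid-body coordinate geometry.

Everything downstream of the structure reader reduces to a handful of
primitives on Cα coordinates: least-squares superposition (Kabsch), RMSD,
pseudo-torsion (virtual-bond) dihedrals, vertex angles between centroids,
and axis--angle decomposition of a rotation about a hinge pivot.  Angles
are in degrees throughout; distances in Å.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "RigidTransform",
    "HingeDecomposition",
    "GeometryError",
    "DegenerateGeometryError",
    "kabsch_superpose",
    "rmsd_after_superposition",
    "dihedral",
    "vertex_angle",
    "centroid",
    "decompose_hinge",
    "rotation_about_axis",
]

_ORTHO_TOL = 1e-9
# collinearity is declared when |u x v| < this factor times |u||v|
_COLLINEAR_TOL = 1e-9


class GeometryError(ValueError):
    """Contract violation in a geometric operation."""


class DegenerateGeometryError(GeometryError):
    """Input configuration is degenerate (collinear/coincident points)."""


def _as_points(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise GeometryError(f"{name}: expected an (n, 3) coordinate array, got shape {arr.shape}")
    if not np.isfinite(arr).all():
        raise GeometryError(f"{name}: non-finite coordinates")
    return arr


def _check_proper_rotation(rot: np.ndarray) -> None:
    if abs(np.linalg.det(rot) - 1.0) > 1e-6:
        raise GeometryError(f"rotation determinant {np.linalg.det(rot):.3g} != +1")
    if np.abs(rot @ rot.T - np.eye(3)).max() > 1e-6:
        raise GeometryError("rotation columns not orthonormal")


@dataclass(frozen=True)
class RigidTransform:
    """Proper rotation plus translation, ``y = R @ x + t``."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        rot = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        tr = np.asarray(self.translation, dtype=float).reshape(3)
        _check_proper_rotation(rot)
        object.__setattr__(self, "rotation", rot)
        object.__setattr__(self, "translation", tr)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)


@dataclass(frozen=True)
class HingeDecomposition:
    """Axis--angle view of a rigid rotation swinging a body about a pivot.

    ``axis`` is a unit vector (undefined for the identity rotation, in which
    case ``axis_defined`` is False and the axis is reported as NaN), ``angle``
    is in degrees in [0, 180], and ``pivot`` is the hinge point the swing arc
    is reported about.
    """

    axis: np.ndarray
    angle: float
    pivot: np.ndarray
    axis_defined: bool = True

    def __post_init__(self):
        ax = np.asarray(self.axis, dtype=float).reshape(3)
        pv = np.asarray(self.pivot, dtype=float).reshape(3)
        if self.axis_defined and abs(np.linalg.norm(ax) - 1.0) > _ORTHO_TOL * 10:
            raise GeometryError("hinge axis must be a unit vector")
        object.__setattr__(self, "axis", ax)
        object.__setattr__(self, "pivot", pv)


def centroid(points) -> np.ndarray:
    """Unweighted arithmetic mean of a point set."""
    pts = _as_points(points, "points")
    if len(pts) == 0:
        raise GeometryError("centroid of an empty point set")
    return pts.mean(axis=0)


def kabsch_superpose(mobile, target) -> tuple[RigidTransform, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``target``.

    Returns the proper rigid transform minimizing the sum of squared paired
    deviations (reflections excluded) and the RMSD after applying it.
    """
    mob = _as_points(mobile, "mobile")
    tgt = _as_points(target, "target")
    if len(mob) != len(tgt):
        raise GeometryError(f"paired coordinate sets differ in length ({len(mob)} vs {len(tgt)})")
    if len(mob) < 3:
        raise GeometryError("need at least 3 paired points for superposition")

    mc, tc = mob.mean(axis=0), tgt.mean(axis=0)
    p, q = mob - mc, tgt - tc

    # conditioning: all points coincident or collinear leaves the rotation
    # about the degenerate direction undetermined
    for pts, name in ((p, "mobile"), (q, "target")):
        s = np.linalg.svd(pts, compute_uv=False)
        if s[1] <= _COLLINEAR_TOL * max(s[0], 1.0):
            raise DegenerateGeometryError(f"{name} points are collinear or coincident")

    h = p.T @ q
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    transform = RigidTransform(rot, tc - rot @ mc)
    moved = transform.apply(mob)
    rmsd = float(np.sqrt(np.mean(np.sum((moved - tgt) ** 2, axis=1))))
    return transform, rmsd


def rmsd_after_superposition(set_a, set_b) -> float:
    """RMSD between two paired coordinate sets after optimal superposition."""
    _, rmsd = kabsch_superpose(set_a, set_b)
    return rmsd


def dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral about the virtual bond p2--p3, degrees in (-180, 180].

    IUPAC sign convention: looking from p2 toward p3, a clockwise rotation of
    the far bond relative to the near bond is positive.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float).reshape(3) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    nb2 = np.linalg.norm(b2)
    if nb2 <= _COLLINEAR_TOL:
        raise DegenerateGeometryError("virtual bond p2-p3 has zero length")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) <= _COLLINEAR_TOL * max(np.linalg.norm(b1) * nb2, 1.0):
        raise DegenerateGeometryError("p1, p2, p3 are collinear")
    if np.linalg.norm(n2) <= _COLLINEAR_TOL * max(np.linalg.norm(b3) * nb2, 1.0):
        raise DegenerateGeometryError("p2, p3, p4 are collinear")
    m1 = np.cross(n1, b2 / nb2)
    x = n1 @ n2
    y = m1 @ n2
    ang = float(np.degrees(np.arctan2(-y, x)))
    # map -180 -> +180 so the range is half-open as documented
    if ang <= -180.0:
        ang += 360.0
    return ang


def vertex_angle(a, vertex, b) -> float:
    """Angle in degrees, in [0, 180], between rays vertex->a and vertex->b."""
    a, v, b = (np.asarray(p, dtype=float).reshape(3) for p in (a, vertex, b))
    u, w = a - v, b - v
    nu, nw = np.linalg.norm(u), np.linalg.norm(w)
    if nu <= _COLLINEAR_TOL or nw <= _COLLINEAR_TOL:
        raise GeometryError("vertex_angle: zero-length ray")
    # atan2 form is stable near 0 and 180 degrees
    return float(np.degrees(np.arctan2(np.linalg.norm(np.cross(u, w)), u @ w)))


def rotation_about_axis(axis, angle_deg: float) -> np.ndarray:
    """Rotation matrix for a right-handed rotation about ``axis`` (Rodrigues)."""
    ax = np.asarray(axis, dtype=float).reshape(3)
    n = np.linalg.norm(ax)
    if n <= _COLLINEAR_TOL:
        raise GeometryError("rotation axis has zero length")
    ax = ax / n
    th = np.radians(angle_deg)
    k = np.array([[0, -ax[2], ax[1]], [ax[2], 0, -ax[0]], [-ax[1], ax[0], 0]])
    return np.eye(3) + np.sin(th) * k + (1 - np.cos(th)) * (k @ k)


def decompose_hinge(transform: RigidTransform, pivot) -> HingeDecomposition:
    """Axis--angle decomposition of the rotation part about a hinge pivot."""
    rot = transform.rotation
    pivot = np.asarray(pivot, dtype=float).reshape(3)
    cos_th = np.clip((np.trace(rot) - 1.0) / 2.0, -1.0, 1.0)
    angle = float(np.degrees(np.arccos(cos_th)))
    if angle < 1e-9:
        return HingeDecomposition(np.full(3, np.nan), 0.0, pivot, axis_defined=False)
    # antisymmetric part gives the axis except near 180 degrees
    w = np.array([rot[2, 1] - rot[1, 2], rot[0, 2] - rot[2, 0], rot[1, 0] - rot[0, 1]])
    if np.linalg.norm(w) > 1e-8:
        axis = w / np.linalg.norm(w)
    else:  # angle ~ 180: axis from the symmetric part
        sym = (rot + np.eye(3)) / 2.0
        axis = sym[:, np.argmax(np.diag(sym))]
        axis = axis / np.linalg.norm(axis)
    return HingeDecomposition(axis, angle, pivot)
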