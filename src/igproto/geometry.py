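"""Rigid-body superposition and symmetry-axis extraction.

The superposition is the standard least-squares orthogonal-Procrustes
solution (Kabsch): given paired point sets P (moving) and Q (fixed), find the
proper rotation R and translation t minimising sum |R p + t - q|^2, with
reflections excluded.  From the optimal transform of a protodomain onto its
symmetry mate we extract the rotation angle, the invariant axis direction,
the screw component (translation along the axis) and a point on the axis --
for an exact C2 the angle is 180 degrees and the screw is zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np


class SingularConfigurationError(ValueError):
    """Point set too degenerate (collinear / <3 pairs) to superpose."""


@dataclass
class SuperpositionResult:
    rotation: np.ndarray      # 3x3, det +1
    translation: np.ndarray   # 3-vector, Angstrom
    rmsd: float               # Angstrom over paired C-alpha
    n_pairs: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class SymmetryAxis:
    direction: np.ndarray   # unit vector
    point: np.ndarray       # a point on the axis, Angstrom
    angle: float            # degrees in (-180, 180]
    screw: float            # Angstrom translation along direction
    order_label: str        # e.g. "C2" or "none"

    def angle_to(self, other: "SymmetryAxis") -> float:
        """Angle between the two axis *lines* in degrees, in [0, 90]."""
        c = abs(float(np.dot(self.direction, other.direction)))
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))

    def distance_to_point(self, p: np.ndarray) -> float:
        d = np.asarray(p, float) - self.point
        return float(np.linalg.norm(d - np.dot(d, self.direction) * self.direction))


def superpose_points(moving: np.ndarray, fixed: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid superposition of ``moving`` onto ``fixed``.

    Both arrays are (n, 3) with index-aligned pairs; n >= 3 non-collinear
    points are required.  Reflection is excluded (det(R) = +1).
    """
    P = np.asarray(moving, float)
    Q = np.asarray(fixed, float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("point sets must be matching (n, 3) arrays")
    n = P.shape[0]
    if n < 3:
        raise SingularConfigurationError(f"need >= 3 pairs, got {n}")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - cp, Q - cq
    # collinearity check: second singular value of the centred moving set
    if np.linalg.svd(P0, compute_uv=False)[1] < 1e-8:
        raise SingularConfigurationError("moving point set is collinear")
    H = P0.T @ Q0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    diff = P @ R.T + t - Q
    rmsd = float(np.sqrt((diff ** 2).sum() / n))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd, n_pairs=n)


def rotation_angle_deg(R: np.ndarray) -> float:
    """Rotation angle from the trace, in [0, 180]."""
    c = (np.trace(R) - 1.0) / 2.0
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def _axis_direction(R: np.ndarray, angle_deg: float) -> np.ndarray:
    if angle_deg < 179.0:
        # skew-symmetric part gives axis * 2 sin(theta)
        v = np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]])
        n = np.linalg.norm(v)
        if n > 1e-9:
            return v / n
    # near 180 deg: invariant eigenvector of R
    w, V = np.linalg.eigh((R + R.T) / 2.0)
    u = V[:, np.argmax(w)]
    # canonical sign: largest-magnitude component positive
    i = int(np.argmax(np.abs(u)))
    if u[i] < 0:
        u = -u
    return u / np.linalg.norm(u)


def symmetry_axis(
    sp: SuperpositionResult,
    paired_centroids: tuple[np.ndarray, np.ndarray],
    c2_tolerance_deg: float = 30.0,
) -> Optional[SymmetryAxis]:
    """Extract the rotation axis of a superposition transform.

    ``paired_centroids`` are the centroids of the two superposed units; the
    reported axis point is the point on the axis nearest their midpoint.
    Returns None (no-axis result) for a near-identity transform.
    """
    R, t = sp.rotation, sp.translation
    angle = rotation_angle_deg(R)
    if angle < 1.0:
        return None  # identity-like: no meaningful axis
    u = _axis_direction(R, angle)
    screw = float(np.dot(t, u))
    # point on axis: solve (I - R) p = t_perp in least squares
    t_perp = t - screw * u
    p0, *_ = np.linalg.lstsq(np.eye(3) - R, t_perp, rcond=None)
    mid = (np.asarray(paired_centroids[0], float)
           + np.asarray(paired_centroids[1], float)) / 2.0
    point = p0 + np.dot(mid - p0, u) * u
    order = "C2" if angle >= 180.0 - c2_tolerance_deg else "none"
    return SymmetryAxis(direction=u, point=point, angle=angle,
                        screw=screw, order_label=order)


def strand_direction(positions: np.ndarray) -> np.ndarray:
    """Unit N-to-C direction of a strand: first principal axis oriented
    from the first to the last C-alpha."""
    X = np.asarray(positions, float)
    X0 = X - X.mean(axis=0)
    _, _, Vt = np.linalg.svd(X0)
    u = Vt[0]
    if np.dot(u, X[-1] - X[0]) < 0:
        u = -u
    return u / np.linalg.norm(u)


def angle_between_deg(u: np.ndarray, v: np.ndarray) -> float:
    c = float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))
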