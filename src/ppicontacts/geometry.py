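"""Small geometric primitives shared across the package."""

from __future__ import annotations

import numpy as np


def unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length vector")
    return v / n


def angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle at vertex ``b`` of the triangle a-b-c, in degrees [0, 180]."""
    u, w = unit(a - b), unit(c - b)
    return float(np.degrees(np.arccos(np.clip(np.dot(u, w), -1.0, 1.0))))


def vector_angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    """Angle between two vectors in degrees [0, 180]."""
    c = np.clip(np.dot(unit(u), unit(v)), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def acute_angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    """Angle between two undirected axes, folded into [0, 90]."""
    a = vector_angle_deg(u, v)
    return min(a, 180.0 - a)


def newell_normal(points: np.ndarray) -> np.ndarray:
    """Unit normal of a (near-)planar polygon by Newell's method.

    Robust to small deviations from planarity; ``points`` must trace the
    polygon perimeter in order.
    """
    pts = np.asarray(points, dtype=float)
    nxt = np.roll(pts, -1, axis=0)
    n = np.array(
        [
            np.sum((pts[:, 1] - nxt[:, 1]) * (pts[:, 2] + nxt[:, 2])),
            np.sum((pts[:, 2] - nxt[:, 2]) * (pts[:, 0] + nxt[:, 0])),
            np.sum((pts[:, 0] - nxt[:, 0]) * (pts[:, 1] + nxt[:, 1])),
        ]
    )
    norm = np.linalg.norm(n)
    if norm < 1e-12:
        raise ValueError("degenerate (collinear) ring: Newell normal undefined")
    return n / norm


def sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    return np.column_stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)]
    )


def rotation_about_axis(axis: np.ndarray, angle_deg_: float) -> np.ndarray:
    """Rotation matrix about ``axis`` (Rodrigues)."""
    a = unit(np.asarray(axis, float))
    t = np.radians(angle_deg_)
    k = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    return np.eye(3) + np.sin(t) * k + (1 - np.cos(t)) * (k @ k)


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle: float, dihedral: float) -> np.ndarray:
    """NeRF placement: position X given antecedents a-b-c with |c-X| = bond,
    angle(b,c,X) = ``angle`` and dihedral(a,b,c,X) = ``dihedral`` (degrees)."""
    ang, dih = np.radians(angle), np.radians(dihedral)
    bc = unit(c - b)
    n = unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d = bond * np.array(
        [-np.cos(ang), np.sin(ang) * np.cos(dih), np.sin(ang) * np.sin(dih)]
    )
    return c + d[0] * bc + d[1] * m + d[2] * n


def kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rotation R and translation t mapping ``mobile`` onto
    ``target`` (both (n,3)); returns (R, t) with x' = x @ R.T + t."""
    mob_c = mobile.mean(axis=0)
    tgt_c = target.mean(axis=0)
    h = (mobile - mob_c).T @ (target - tgt_c)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    r = vt.T @ corr @ u.T
    t = tgt_c - mob_c @ r.T
    return r, t
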