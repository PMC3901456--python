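"""Rigid-body superposition, dihedral angles and sphere sampling."""

from __future__ import annotations

import numpy as np


class DegenerateInputError(ValueError):
    """Raised when a geometric operation receives a degenerate point set."""


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray):
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` minimises the RMSD to
    ``reference`` over all proper rigid transforms (Kabsch, via SVD).

    Parameters
    ----------
    mobile, reference
        ``(n, 3)`` coordinate arrays with ``n >= 3`` non-collinear points.

    Raises
    ------
    DegenerateInputError
        For fewer than 3 points or a collinear point set, where the
        optimal rotation is not unique.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError(
            f"coordinate sets must share an (n, 3) shape, got "
            f"{mobile.shape} and {reference.shape}"
        )
    n = mobile.shape[0]
    if n < 3:
        raise DegenerateInputError(f"need >= 3 points, got {n}")

    mob_c = mobile - mobile.mean(axis=0)
    ref_c = reference - reference.mean(axis=0)
    # Collinear (rank < 2) sets leave a free rotation about the line.
    if np.linalg.matrix_rank(mob_c, tol=1e-8) < 2:
        raise DegenerateInputError("collinear point set")

    h = mob_c.T @ ref_c
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rotation = vt.T @ corr @ u.T
    translation = reference.mean(axis=0) - rotation @ mobile.mean(axis=0)

    # Measure the deviation directly: unlike the E0 - 2*trace(S) identity
    # this does not lose precision when the minimum is near zero.
    delta = mob_c @ rotation.T - ref_c
    msd = float((delta**2).sum()) / n
    return rotation, translation, float(np.sqrt(msd))


def apply_transform(coords: np.ndarray, rotation: np.ndarray, translation: np.ndarray) -> np.ndarray:
    return coords @ rotation.T + translation


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle in degrees, in ``(-180, 180]``.

    Standard IUPAC convention: looking from ``p1`` to ``p2``, the angle is
    positive for a clockwise rotation of ``p3`` relative to ``p0``.
    """
    b0 = np.asarray(p0, float) - np.asarray(p1, float)
    b1 = np.asarray(p2, float) - np.asarray(p1, float)
    b2 = np.asarray(p3, float) - np.asarray(p2, float)
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - (b0 @ b1) * b1
    w = b2 - (b2 @ b1) * b1
    x = v @ w
    y = np.cross(b1, v) @ w
    ang = np.degrees(np.arctan2(y, x))
    return 180.0 if np.isclose(ang, -180.0) else float(ang)


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotation matrix for a right-handed rotation about ``axis``."""
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    t = np.radians(angle_deg)
    c, s = np.cos(t), np.sin(t)
    x, y, z = axis
    k = np.array([[0.0, -z, y], [z, 0.0, -x], [-y, x, 0.0]])
    return c * np.eye(3) + s * k + (1 - c) * np.outer(axis, axis)


def sphere_points(n: int) -> np.ndarray:
    """``n`` quasi-uniform points on the unit sphere (golden-spiral lattice)."""
    if n < 1:
        raise ValueError("need at least one sphere point")
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    return np.column_stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)]
    )


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Place a fourth point from three anchors and internal coordinates.

    The new point ``d`` sits at distance ``bond`` from ``c``, with angle
    ``b-c-d`` equal to ``angle_deg`` and dihedral ``a-b-c-d`` equal to
    ``dihedral_deg`` (NeRF construction).
    """
    a, b, c = (np.asarray(v, float) for v in (a, b, c))
    ang = np.radians(angle_deg)
    dih = np.radians(dihedral_deg)
    d_local = np.array(
        [
            -bond * np.cos(ang),
            bond * np.sin(ang) * np.cos(dih),
            bond * np.sin(ang) * np.sin(dih),
        ]
    )
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.column_stack([bc, np.cross(n, bc), n])
    return c + m @ d_local
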