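"""Ellipse/tangent geometry turning a segmentation into the angle of progression.

The angle of progression (AoP) is the angle, at the inferior (right) endpoint
of the pubic symphysis (PS), between the PS long axis and the line tangent to
the fetal-head (FH) contour.  This module provides the post-processing chain:

    mask_boundary -> fit_ellipse -> tangent_points -> select_tangent -> compute_aop

All coordinates are 0-based pixel coordinates, ``x`` rightward, ``y`` downward,
pixel centers at integer coordinates.  The conic sign convention used
throughout is ``A > 0`` so that the interior of an ellipse evaluates negative
and the exterior positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure as _skmeasure

__all__ = [
    "Ellipse",
    "AoPResult",
    "GeometryError",
    "mask_boundary",
    "fit_ellipse",
    "tangent_points",
    "select_tangent",
    "compute_aop",
    "measure",
]


class GeometryError(ValueError):
    """Raised when a geometric construction is impossible (degenerate input)."""


# ---------------------------------------------------------------------------
# Ellipse representation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Ellipse:
    """An ellipse in both geometric and conic (implicit) form.

    Parameters
    ----------
    center : (x, y) in pixels.
    a, b : semi-major / semi-minor axis lengths, ``a >= b > 0``.
    angle_deg : orientation of the major axis against +x, degrees.
    conic : coefficients ``(A, B, C, D, E, F)`` of
        ``A x^2 + B x y + C y^2 + D x + E y + F = 0``, normalized to unit
        Euclidean norm with ``A > 0``.
    """

    center: tuple[float, float]
    a: float
    b: float
    angle_deg: float
    conic: tuple[float, float, float, float, float, float] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not (self.a >= self.b > 0):
            raise GeometryError(f"require a >= b > 0, got a={self.a}, b={self.b}")
        if self.conic is None:
            object.__setattr__(self, "conic", _geometric_to_conic(
                self.center, self.a, self.b, self.angle_deg))

    @classmethod
    def from_conic(cls, coeffs) -> "Ellipse":
        coeffs = _normalize_conic(np.asarray(coeffs, dtype=float))
        center, a, b, angle = _conic_to_geometric(coeffs)
        return cls(center=center, a=a, b=b, angle_deg=angle, conic=tuple(coeffs))

    @property
    def conic_matrix(self) -> np.ndarray:
        """Symmetric 3x3 matrix Q with p^T Q p = 0 on the ellipse."""
        A, B, C, D, E, F = self.conic
        return np.array([
            [A, B / 2, D / 2],
            [B / 2, C, E / 2],
            [D / 2, E / 2, F],
        ])

    def evaluate(self, point) -> float:
        """Signed conic value: negative inside, ~0 on, positive outside."""
        x, y = point
        A, B, C, D, E, F = self.conic
        return A * x * x + B * x * y + C * y * y + D * x + E * y + F

    def point_at(self, t: float) -> tuple[float, float]:
        """Point on the ellipse at parametric angle ``t`` (radians)."""
        phi = np.deg2rad(self.angle_deg)
        cx, cy = self.center
        x = cx + self.a * np.cos(t) * np.cos(phi) - self.b * np.sin(t) * np.sin(phi)
        y = cy + self.a * np.cos(t) * np.sin(phi) + self.b * np.sin(t) * np.cos(phi)
        return (float(x), float(y))


def _normalize_conic(c: np.ndarray) -> np.ndarray:
    n = float(np.linalg.norm(c))
    if n == 0:
        raise GeometryError("zero conic")
    c = c / n
    # sign so that A > 0 (interior of an ellipse negative)
    if c[0] < 0:
        c = -c
    return c


def _geometric_to_conic(center, a, b, angle_deg):
    cx, cy = center
    phi = np.deg2rad(angle_deg)
    c, s = np.cos(phi), np.sin(phi)
    # ((x-cx)c + (y-cy)s)^2/a^2 + (-(x-cx)s + (y-cy)c)^2/b^2 = 1
    A = c * c / a**2 + s * s / b**2
    B = 2 * c * s * (1 / a**2 - 1 / b**2)
    C = s * s / a**2 + c * c / b**2
    D = -2 * A * cx - B * cy
    E = -B * cx - 2 * C * cy
    F = A * cx * cx + B * cx * cy + C * cy * cy - 1
    return tuple(_normalize_conic(np.array([A, B, C, D, E, F])))


def _conic_to_geometric(coeffs):
    A, B, C, D, E, F = coeffs
    disc = B * B - 4 * A * C
    if disc >= 0:
        raise GeometryError("conic is not an ellipse (B^2 - 4AC >= 0)")
    # center from gradient = 0
    cx = (2 * C * D - B * E) / disc
    cy = (2 * A * E - B * D) / disc
    # axes from the eigenvalues of the quadratic part
    Fc = A * cx * cx + B * cx * cy + C * cy * cy + D * cx + E * cy + F
    if Fc >= 0:
        raise GeometryError("degenerate ellipse (no interior)")
    M = np.array([[A, B / 2], [B / 2, C]])
    evals, evecs = np.linalg.eigh(M)
    # (p - c)^T M (p - c) = -Fc  =>  semi-axis along eigvec i is sqrt(-Fc/eval_i)
    if np.any(evals <= 0):
        raise GeometryError("conic is not an ellipse (quadratic part not definite)")
    axes = np.sqrt(-Fc / evals)
    i_major = int(np.argmax(axes))
    a, b = float(axes[i_major]), float(axes[1 - i_major])
    v = evecs[:, i_major]
    angle = float(np.rad2deg(np.arctan2(v[1], v[0]))) % 180.0
    return (float(cx), float(cy)), a, b, angle


# ---------------------------------------------------------------------------
# Contour extraction and direct least-squares fitting
# ---------------------------------------------------------------------------

def mask_boundary(mask: np.ndarray, class_id: int) -> np.ndarray:
    """Ordered outer boundary of the largest connected component of a class.

    Returns an (N, 2) array of (x, y) points (subpixel, from the 0.5 level
    contour of the binary component).  Raises :class:`GeometryError` if the
    class has fewer than 5 pixels or the boundary is too short to determine
    an ellipse.
    """
    binary = np.asarray(mask) == class_id
    if binary.sum() < 5:
        raise GeometryError("no FH region")
    labels, n = ndimage.label(binary)
    if n > 1:
        sizes = ndimage.sum_labels(binary, labels, index=np.arange(1, n + 1))
        binary = labels == (1 + int(np.argmax(sizes)))
    padded = np.pad(binary.astype(float), 1)
    contours = _skmeasure.find_contours(padded, 0.5)
    if not contours:
        raise GeometryError("no boundary")
    contour = max(contours, key=len)
    # find_contours yields (row, col); un-pad and swap to (x, y)
    pts = np.stack([contour[:, 1] - 1.0, contour[:, 0] - 1.0], axis=1)
    if len(pts) < 5:
        raise GeometryError("boundary underdetermined (<5 points)")
    return pts


def fit_ellipse(points: np.ndarray) -> Ellipse:
    """Direct least-squares ellipse fit (conic constrained by 4AC - B^2 = 1).

    Uses the numerically stabilized partitioning of the classic direct fit:
    the quadratic part is solved from a 3x3 eigenproblem whose constraint
    matrix guarantees an elliptical solution, the linear part follows by
    back-substitution.  Input is an (N, 2) array of (x, y) with N >= 5.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 5:
        raise GeometryError("need >= 5 (x, y) points")
    mean = pts.mean(axis=0)
    x, y = (pts - mean).T  # center for conditioning
    D1 = np.stack([x * x, x * y, y * y], axis=1)
    D2 = np.stack([x, y, np.ones_like(x)], axis=1)
    S1 = D1.T @ D1
    S2 = D1.T @ D2
    S3 = D2.T @ D2
    try:
        T = -np.linalg.solve(S3, S2.T)
    except np.linalg.LinAlgError as exc:
        raise GeometryError("degenerate point configuration") from exc
    M = S1 + S2 @ T
    # premultiply by inv(C) for constraint 4AC - B^2 = 1
    M = np.array([M[2] / 2.0, -M[1], M[0] / 2.0])
    evals, evecs = np.linalg.eig(M)
    cond = 4 * evecs[0] * evecs[2] - evecs[1] ** 2
    ok = np.where(np.isreal(evals) & (cond > 0))[0]
    if len(ok) == 0:
        raise GeometryError("no elliptical solution (collinear or degenerate points)")
    a1 = np.real(evecs[:, ok[0]])
    coeffs_centered = np.concatenate([a1, T @ a1])
    # undo the centering shift
    A, B, C, D, E, F = coeffs_centered
    mx, my = mean
    Dn = D - 2 * A * mx - B * my
    En = E - B * mx - 2 * C * my
    Fn = F + A * mx * mx + B * mx * my + C * my * my - D * mx - E * my
    return Ellipse.from_conic([A, B, C, Dn, En, Fn])


# ---------------------------------------------------------------------------
# Tangent construction and the angle
# ---------------------------------------------------------------------------

def tangent_points(ellipse: Ellipse, external_point) -> tuple[tuple[float, float], tuple[float, float]]:
    """The two tangency points of the tangent lines from an external point.

    Intersects the polar line (chord of contact) of the point with the conic.
    Raises :class:`GeometryError` when the point is inside or on the ellipse.
    """
    px, py = external_point
    if ellipse.evaluate((px, py)) <= 1e-12:
        raise GeometryError("no tangent: point inside or on the ellipse")
    Q = ellipse.conic_matrix
    line = Q @ np.array([px, py, 1.0])  # polar line: l . (x, y, 1) = 0
    lx, ly, lc = line
    nrm2 = lx * lx + ly * ly
    if nrm2 < 1e-30:
        raise GeometryError("degenerate polar line")
    p0 = np.array([-lc * lx / nrm2, -lc * ly / nrm2, 1.0])  # closest point to origin
    d = np.array([ly, -lx, 0.0]) / np.sqrt(nrm2)  # unit direction along the line
    # (p0 + t d)^T Q (p0 + t d) = 0
    qa = d @ Q @ d
    qb = 2.0 * (d @ Q @ p0)
    qc = p0 @ Q @ p0
    disc = qb * qb - 4 * qa * qc
    if disc < 0 or abs(qa) < 1e-30:
        raise GeometryError("polar line does not meet the ellipse")
    r = np.sqrt(disc)
    t1, t2 = (-qb - r) / (2 * qa), (-qb + r) / (2 * qa)
    pt1 = p0 + t1 * d
    pt2 = p0 + t2 * d
    return ((float(pt1[0]), float(pt1[1])), (float(pt2[0]), float(pt2[1])))


def _angle_at(vertex, toward_a, toward_b) -> float:
    u = np.asarray(toward_a, float) - np.asarray(vertex, float)
    v = np.asarray(toward_b, float) - np.asarray(vertex, float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise GeometryError("coincident points")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def select_tangent(candidates, left_endpoint, right_endpoint, rule: str = "max-angle"):
    """Pick the tangency point on the leading (distal) head contour.

    Of the two candidates, returns the one forming the larger angle at the
    right PS endpoint between the ray toward the left endpoint and the ray
    toward the candidate (``rule="min-angle"`` selects the other).  Ties are
    broken toward larger ``y``.
    """
    if rule not in ("max-angle", "min-angle"):
        raise ValueError(f"unknown tangent selection rule: {rule!r}")
    angles = [_angle_at(right_endpoint, left_endpoint, c) for c in candidates]
    better = max if rule == "max-angle" else min
    if abs(angles[0] - angles[1]) < 1e-9:
        return max(candidates, key=lambda c: c[1])
    return candidates[0] if better(angles) == angles[0] else candidates[1]


def compute_aop(left_endpoint, right_endpoint, tangent_point) -> float:
    """AoP in degrees: angle at the right endpoint between the ray to the
    left endpoint and the ray to the tangent point, in (0, 180]."""
    return _angle_at(right_endpoint, left_endpoint, tangent_point)


# ---------------------------------------------------------------------------
# The composed measurement
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AoPResult:
    """Outcome of one AoP measurement (three key points + angle)."""

    valid: bool
    left_endpoint: tuple[float, float] | None = None
    right_endpoint: tuple[float, float] | None = None
    tangent_point: tuple[float, float] | None = None
    aop_deg: float = float("nan")
    ellipse: Ellipse | None = None
    reason: str = ""


def measure(seg_mask: np.ndarray, endpoints, fh_class: int = 2,
            tangent_rule: str = "max-angle") -> AoPResult:
    """Measure AoP from a segmentation mask and the two PS endpoints.

    ``endpoints`` is ``(left, right)`` in the mask's pixel frame.  Each stage
    failure is reported through ``valid=False`` and ``reason`` instead of an
    exception, so a batch evaluation can tabulate failures.
    """
    left, right = (tuple(map(float, endpoints[0])), tuple(map(float, endpoints[1])))
    try:
        boundary = mask_boundary(seg_mask, fh_class)
    except GeometryError as exc:
        return AoPResult(valid=False, left_endpoint=left, right_endpoint=right,
                         reason=str(exc))
    try:
        ellipse = fit_ellipse(boundary)
    except GeometryError as exc:
        return AoPResult(valid=False, left_endpoint=left, right_endpoint=right,
                         reason=f"ellipse fit failed: {exc}")
    try:
        cands = tangent_points(ellipse, right)
    except GeometryError:
        return AoPResult(valid=False, left_endpoint=left, right_endpoint=right,
                         ellipse=ellipse, reason="no tangent")
    try:
        tp = select_tangent(cands, left, right, rule=tangent_rule)
        aop = compute_aop(left, right, tp)
    except GeometryError as exc:
        return AoPResult(valid=False, left_endpoint=left, right_endpoint=right,
                         ellipse=ellipse, reason=str(exc))
    return AoPResult(valid=True, left_endpoint=left, right_endpoint=right,
                     tangent_point=tp, aop_deg=aop, ellipse=ellipse)
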