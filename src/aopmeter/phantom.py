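"""Seeded synthetic transperineal-ultrasound-like phantoms with exact truth.

Each standard-plane phantom contains a bright convex elliptical fetal-head
(FH) region and an elongated pubic-symphysis (PS) capsule whose two axis
endpoints are the landmark ground truth.  The generating shapes are stored on
the sample, so the analytic angle of progression (AoP) — computed from the
true ellipse and the true endpoints via the same tangent construction used at
measurement time — is exact, not rasterization-limited.  Nonstandard-plane
phantoms drop or truncate structures so that standard-plane recognition is a
meaningful task.

The speckle model is deliberately simple: multiplicative Gaussian noise
``image * (1 + strength * g)`` clipped to [0, 255].  It defeats trivial
global thresholding but does not emulate attenuation, shadowing or the
log-compressed Rayleigh statistics of real B-mode speckle.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from . import geometry
from .geometry import Ellipse

__all__ = [
    "PhantomSpec",
    "PhantomSample",
    "PhantomError",
    "NONSTANDARD_MODES",
    "generate_standard",
    "generate_nonstandard",
    "generate_dataset",
    "save_image",
    "save_mask",
]

NONSTANDARD_MODES = ("missing_fh", "missing_ps", "truncated", "noise_only")

#: mask labels
BACKGROUND, PS, FH = 0, 1, 2


class PhantomError(RuntimeError):
    """Raised when a spec's ranges cannot produce a valid sample."""


@dataclass(frozen=True)
class PhantomSpec:
    """Sampling ranges for the phantom geometry (desk-scale defaults, 96x96).

    Angles in degrees, lengths in pixels.  ``fh_approach_angle_range`` is the
    direction of the ray from the FH center toward the PS right endpoint
    (~180 deg = PS straight to the left of the head).  ``ps_angle_range`` is
    the direction of the PS axis from its left to its right endpoint, so
    values in (-90, 90) guarantee ``right.x > left.x``.
    """

    image_height: int = 96
    image_width: int = 96
    fh_center_range: tuple[tuple[float, float], tuple[float, float]] = ((54.0, 70.0), (46.0, 62.0))
    fh_axes_range: tuple[tuple[float, float], tuple[float, float]] = ((16.0, 24.0), (12.0, 17.0))
    fh_angle_range: tuple[float, float] = (0.0, 180.0)
    fh_approach_angle_range: tuple[float, float] = (160.0, 215.0)
    ps_length_range: tuple[float, float] = (20.0, 32.0)
    ps_width_range: tuple[float, float] = (4.0, 7.0)
    ps_angle_range: tuple[float, float] = (-25.0, 25.0)
    gap_range: tuple[float, float] = (4.0, 12.0)
    speckle_strength: float = 0.15
    pixel_spacing_mm: float = 0.2
    nonstandard_modes: tuple[str, ...] = NONSTANDARD_MODES
    background_intensity: float = 30.0
    ps_intensity: float = 220.0
    fh_intensity: float = 170.0
    margin: float = 2.0
    max_attempts: int = 500

    def __post_init__(self) -> None:
        for name in ("fh_angle_range", "fh_approach_angle_range", "ps_length_range",
                     "ps_width_range", "ps_angle_range", "gap_range"):
            lo, hi = getattr(self, name)
            if hi < lo:
                raise ValueError(f"{name} is empty: {(lo, hi)}")
        for name in ("fh_center_range", "fh_axes_range"):
            for lo, hi in getattr(self, name):
                if hi < lo:
                    raise ValueError(f"{name} is empty")
        unknown = set(self.nonstandard_modes) - set(NONSTANDARD_MODES)
        if unknown:
            raise ValueError(f"unknown nonstandard modes: {sorted(unknown)}")
        if self.image_height < 16 or self.image_width < 16:
            raise ValueError("image too small")


@dataclass(frozen=True)
class PhantomSample:
    """One phantom image with ground truth for all three network tasks."""

    image: np.ndarray                       # (H, W) uint8
    mask: np.ndarray                        # (H, W) uint8 in {0, 1, 2}
    left_endpoint: tuple[float, float]      # (x, y), NaN for nonstandard w/o PS
    right_endpoint: tuple[float, float]
    aop_true: float                         # degrees; NaN if nonstandard
    is_standard: bool
    patient_id: str
    seed: int
    fh_ellipse: Ellipse | None = None       # generating shapes (analytic truth)
    ps_width: float = float("nan")
    mode: str = "standard"


# ---------------------------------------------------------------------------
# rasterization helpers
# ---------------------------------------------------------------------------

def _pixel_grid(h: int, w: int):
    y, x = np.mgrid[0:h, 0:w]
    return x.astype(float), y.astype(float)


def _rasterize_ellipse(ellipse: Ellipse, h: int, w: int) -> np.ndarray:
    x, y = _pixel_grid(h, w)
    A, B, C, D, E, F = ellipse.conic
    return (A * x * x + B * x * y + C * y * y + D * x + E * y + F) <= 0


def _rasterize_capsule(p0, p1, width: float, h: int, w: int) -> np.ndarray:
    """Capsule = all pixels within width/2 of the segment p0-p1."""
    x, y = _pixel_grid(h, w)
    p0 = np.asarray(p0, float)
    d = np.asarray(p1, float) - p0
    len2 = float(d @ d)
    t = ((x - p0[0]) * d[0] + (y - p0[1]) * d[1]) / max(len2, 1e-12)
    t = np.clip(t, 0.0, 1.0)
    dx = x - (p0[0] + t * d[0])
    dy = y - (p0[1] + t * d[1])
    return dx * dx + dy * dy <= (width / 2.0) ** 2


def _ray_exit_distance(ellipse: Ellipse, direction_deg: float) -> float:
    """Distance from the ellipse center to its boundary along a direction."""
    cx, cy = ellipse.center
    u = np.array([np.cos(np.deg2rad(direction_deg)), np.sin(np.deg2rad(direction_deg))])
    Q = ellipse.conic_matrix
    p0 = np.array([cx, cy, 1.0])
    dh = np.array([u[0], u[1], 0.0])
    qa = dh @ Q @ dh
    qb = 2 * (dh @ Q @ p0)
    qc = p0 @ Q @ p0
    disc = qb * qb - 4 * qa * qc
    r = np.sqrt(max(disc, 0.0))
    return float(max((-qb + r) / (2 * qa), (-qb - r) / (2 * qa)))


def _render(spec: PhantomSpec, mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    img = np.full(mask.shape, spec.background_intensity, dtype=float)
    img[mask == PS] = spec.ps_intensity
    img[mask == FH] = spec.fh_intensity
    if spec.speckle_strength > 0:
        g = rng.standard_normal(mask.shape)
        img = img * (1.0 + spec.speckle_strength * g)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def _sample_geometry(spec: PhantomSpec, rng: np.random.Generator):
    """Draw one FH ellipse + PS capsule satisfying all placement constraints.

    Returns (ellipse, left, right, width, aop) or None if the draw violates
    a constraint (caller retries).
    """
    (cxr, cyr) = spec.fh_center_range
    (ar, br) = spec.fh_axes_range
    cx = rng.uniform(*cxr)
    cy = rng.uniform(*cyr)
    a = rng.uniform(*ar)
    b = rng.uniform(*br)
    if b > a:
        a, b = b, a
    angle = rng.uniform(*spec.fh_angle_range)
    approach = rng.uniform(*spec.fh_approach_angle_range)
    gap = rng.uniform(*spec.gap_range)
    length = rng.uniform(*spec.ps_length_range)
    width = rng.uniform(*spec.ps_width_range)
    ps_angle = rng.uniform(*spec.ps_angle_range)

    ellipse = Ellipse(center=(cx, cy), a=a, b=b, angle_deg=angle)
    h, w, m = spec.image_height, spec.image_width, spec.margin
    # FH fully inside the frame (conservative: bounding circle of radius a)
    if not (m <= cx - a and cx + a <= w - 1 - m and m <= cy - a and cy + a <= h - 1 - m):
        return None

    t_exit = _ray_exit_distance(ellipse, approach)
    u = np.array([np.cos(np.deg2rad(approach)), np.sin(np.deg2rad(approach))])
    right = np.array([cx, cy]) + (t_exit + gap) * u
    d = np.array([np.cos(np.deg2rad(ps_angle)), np.sin(np.deg2rad(ps_angle))])
    left = right - length * d
    if left[0] >= right[0]:
        return None
    hw = width / 2.0 + 1.0
    for pt in (left, right):
        if not (hw + m <= pt[0] <= w - 1 - hw - m and hw + m <= pt[1] <= h - 1 - hw - m):
            return None
    # PS capsule must clear the FH boundary
    boundary = np.stack([ellipse.point_at(t) for t in np.linspace(0, 2 * np.pi, 256, endpoint=False)])
    seg = right - left
    len2 = float(seg @ seg)
    t = np.clip(((boundary - left) @ seg) / len2, 0.0, 1.0)
    closest = left + t[:, None] * seg
    if np.min(np.linalg.norm(boundary - closest, axis=1)) <= width / 2.0 + 1.5:
        return None
    try:
        cands = geometry.tangent_points(ellipse, tuple(right))
        tp = geometry.select_tangent(cands, tuple(left), tuple(right))
        aop = geometry.compute_aop(tuple(left), tuple(right), tp)
    except geometry.GeometryError:
        return None
    if not (0.0 < aop < 180.0):
        return None
    return ellipse, tuple(left), tuple(right), width, aop


def generate_standard(spec: PhantomSpec, patient_id: str, seed: int) -> PhantomSample:
    """One standard-plane phantom (both PS and FH present)."""
    rng = np.random.default_rng(seed)
    for _ in range(spec.max_attempts):
        drawn = _sample_geometry(spec, rng)
        if drawn is not None:
            break
    else:
        raise PhantomError(
            f"no valid geometry in {spec.max_attempts} attempts; ranges incompatible")
    ellipse, left, right, width, aop = drawn
    h, w = spec.image_height, spec.image_width
    mask = np.zeros((h, w), dtype=np.uint8)
    mask[_rasterize_ellipse(ellipse, h, w)] = FH
    mask[_rasterize_capsule(left, right, width, h, w)] = PS
    image = _render(spec, mask, rng)
    return PhantomSample(image=image, mask=mask, left_endpoint=left,
                         right_endpoint=right, aop_true=aop, is_standard=True,
                         patient_id=patient_id, seed=seed, fh_ellipse=ellipse,
                         ps_width=width, mode="standard")


def generate_nonstandard(spec: PhantomSpec, patient_id: str, seed: int) -> PhantomSample:
    """One nonstandard-plane phantom (a structure absent or truncated)."""
    if not spec.nonstandard_modes:
        raise ValueError("nonstandard_modes is empty")
    rng = np.random.default_rng(seed)
    mode = str(rng.choice(list(spec.nonstandard_modes)))
    h, w = spec.image_height, spec.image_width
    mask = np.zeros((h, w), dtype=np.uint8)
    nan2 = (float("nan"), float("nan"))
    left = right = nan2
    ellipse = None
    width = float("nan")

    if mode != "noise_only":
        for _ in range(spec.max_attempts):
            drawn = _sample_geometry(spec, rng)
            if drawn is not None:
                break
        else:
            raise PhantomError("no valid geometry for nonstandard sample")
        ellipse, left, right, width, _aop = drawn
        if mode == "missing_fh":
            mask[_rasterize_capsule(left, right, width, h, w)] = PS
            ellipse = None
        elif mode == "missing_ps":
            mask[_rasterize_ellipse(ellipse, h, w)] = FH
            left = right = nan2
            width = float("nan")
        elif mode == "truncated":
            # push the FH mostly out of the frame; PS kept in place
            cx, cy = ellipse.center
            shift = (w - 1) - cx + ellipse.a * rng.uniform(0.3, 0.8)
            ellipse = Ellipse(center=(cx + shift, cy), a=ellipse.a, b=ellipse.b,
                              angle_deg=ellipse.angle_deg)
            mask[_rasterize_ellipse(ellipse, h, w)] = FH
            mask[_rasterize_capsule(left, right, width, h, w)] = PS
    image = _render(spec, mask, rng)
    return PhantomSample(image=image, mask=mask, left_endpoint=left,
                         right_endpoint=right, aop_true=float("nan"),
                         is_standard=False, patient_id=patient_id, seed=seed,
                         fh_ellipse=ellipse, ps_width=width, mode=mode)


# ---------------------------------------------------------------------------
# dataset on disk
# ---------------------------------------------------------------------------

def save_image(image: np.ndarray, path) -> None:
    Image.fromarray(image, mode="L").save(path)


_PALETTE = [0, 0, 0, 0, 200, 0, 200, 0, 0] + [0] * (256 * 3 - 9)


def save_mask(mask: np.ndarray, path) -> None:
    im = Image.fromarray(mask.astype(np.uint8), mode="P")
    im.putpalette(_PALETTE)
    im.save(path)


def sample_seed(root_seed: int, index: int) -> int:
    """Deterministic per-sample seed derived from a root seed."""
    return int(np.random.SeedSequence([root_seed, index]).generate_state(1)[0] % (2**31))


def generate_samples(spec: PhantomSpec, n_standard: int, n_nonstandard: int,
                     n_patients: int, seed: int) -> list[PhantomSample]:
    """In-memory dataset; patients assigned round-robin over all samples."""
    if n_patients < 3:
        raise ValueError("need >= 3 patients for a patient-wise 5:2:3 split")
    samples = []
    total = n_standard + n_nonstandard
    for i in range(total):
        pid = f"P{i % n_patients:03d}"
        s = sample_seed(seed, i)
        if i < n_standard:
            samples.append(generate_standard(spec, pid, s))
        else:
            samples.append(generate_nonstandard(spec, pid, s))
    return samples


def generate_dataset(spec: PhantomSpec, n_standard: int, n_nonstandard: int,
                     n_patients: int, seed: int, out_dir) -> Path:
    """Write images, masks and a manifest CSV; returns the manifest path.

    Manifest columns: image_path, mask_path, patient_id, is_standard,
    xl, yl, xr, yr, aop_true (paths relative to ``out_dir``).
    """
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    rows = []
    for i, s in enumerate(generate_samples(spec, n_standard, n_nonstandard, n_patients, seed)):
        img_rel = f"images/{i:05d}.png"
        msk_rel = f"masks/{i:05d}.png"
        save_image(s.image, out_dir / img_rel)
        save_mask(s.mask, out_dir / msk_rel)
        rows.append({
            "image_path": img_rel, "mask_path": msk_rel,
            "patient_id": s.patient_id, "is_standard": s.is_standard,
            "xl": s.left_endpoint[0], "yl": s.left_endpoint[1],
            "xr": s.right_endpoint[0], "yr": s.right_endpoint[1],
            "aop_true": s.aop_true,
        })
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def spec_to_dict(spec: PhantomSpec) -> dict:
    return dataclasses.asdict(spec)


def spec_from_dict(d: dict) -> PhantomSpec:
    def _tup(v):
        return tuple(_tup(x) for x in v) if isinstance(v, (list, tuple)) else v
    return PhantomSpec(**{k: _tup(v) for k, v in d.items()})
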