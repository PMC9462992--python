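"""Manifest loading, preprocessing, augmentation, heatmaps and patient split.

Network-facing conventions:

* images are resized to ``target_size`` (H', W') — default (384, 416), i.e.
  width 416 x height 384 — and intensity-mapped linearly from [0, 255] to
  [-1, 1];
* endpoint heatmaps are unit-peak Gaussians, one per landmark, ordered
  (right endpoint, left endpoint, PS-axis midpoint).  The midpoint map is an
  auxiliary third target whose loss weight is lowest; only the first two maps
  are decoded back to coordinates;
* every spatial transform applied to the image is applied with identical
  parameters to the mask, the endpoints and (by rebuild) the heatmaps.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage
from skimage.transform import resize as _sk_resize

__all__ = [
    "SpatialMap", "Sample", "SplitPlan", "DetectionError",
    "preprocess", "make_heatmaps", "extract_endpoints", "augment",
    "split_by_patient", "load_manifest", "load_samples",
]

DEFAULT_TARGET_SIZE = (384, 416)  # (H', W')
DEFAULT_SIGMA = 6.0               # heatmap Gaussian sigma, px at network resolution


class DetectionError(RuntimeError):
    """Raised when a landmark cannot be decoded (all-zero heatmap)."""


@dataclass(frozen=True)
class SpatialMap:
    """Pure-scale map between original and network pixel coordinates."""

    sx: float
    sy: float

    def apply(self, point):
        return (point[0] * self.sx, point[1] * self.sy)

    def invert(self, point):
        return (point[0] / self.sx, point[1] / self.sy)


@dataclass(frozen=True)
class Sample:
    """One network-ready sample (all arrays at network resolution)."""

    image: np.ndarray                 # (H', W') float32 in [-1, 1]
    mask: np.ndarray                  # (H', W') uint8 in {0, 1, 2}
    heatmaps: np.ndarray              # (3, H', W') float32 in [0, 1]
    class_label: int                  # 0 nonstandard, 1 standard
    endpoints: tuple | None           # ((xl, yl), (xr, yr)) network coords
    spatial_map: SpatialMap
    transform_record: dict
    patient_id: str = ""
    aop_true: float = float("nan")
    image_path: str = ""


@dataclass(frozen=True)
class SplitPlan:
    train_ids: tuple
    val_ids: tuple
    test_ids: tuple
    ratios: tuple = (5, 2, 3)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def preprocess(image_raw: np.ndarray, target_size=DEFAULT_TARGET_SIZE):
    """Bilinear resize + linear [0,255] -> [-1,1]; returns (image, SpatialMap)."""
    img = np.asarray(image_raw, dtype=np.float64)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("expected a non-empty single-channel image")
    h, w = img.shape
    th, tw = target_size
    if (h, w) != (th, tw):
        img = _sk_resize(img, (th, tw), order=1, preserve_range=True,
                         anti_aliasing=False)
    img = img / 255.0 * 2.0 - 1.0
    return img.astype(np.float32), SpatialMap(sx=tw / w, sy=th / h)


def make_heatmaps(endpoints, shape, sigma: float = DEFAULT_SIGMA) -> np.ndarray:
    """Unit-peak Gaussian heatmaps for (right, left, midpoint).

    ``endpoints`` is ((xl, yl), (xr, yr)); ``shape`` is (H, W).
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    (xl, yl), (xr, yr) = endpoints
    h, w = shape
    for x, y in ((xl, yl), (xr, yr)):
        if not (0 <= x <= w - 1 and 0 <= y <= h - 1):
            raise ValueError(f"endpoint ({x}, {y}) outside image {shape}")
    centers = [(xr, yr), (xl, yl), ((xl + xr) / 2.0, (yl + yr) / 2.0)]
    yy, xx = np.mgrid[0:h, 0:w]
    maps = np.empty((3, h, w), dtype=np.float32)
    for k, (cx, cy) in enumerate(centers):
        maps[k] = np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2.0 * sigma**2))
    return maps


def extract_endpoints(heatmaps: np.ndarray, spatial_map: SpatialMap):
    """Decode (left, right) endpoints in original coordinates via per-map argmax.

    Map 0 is the right endpoint, map 1 the left.  Ties break row-major first.
    """
    hm = np.asarray(heatmaps)
    if np.any(hm < 0):
        raise ValueError("heatmaps must be nonnegative")
    pts_net = []
    for k in (0, 1):
        if hm[k].max() <= 0:
            raise DetectionError(f"all-zero heatmap {k}")
        flat = int(np.argmax(hm[k]))
        y, x = divmod(flat, hm[k].shape[1])
        pts_net.append((float(x), float(y)))
    right = spatial_map.invert(pts_net[0])
    left = spatial_map.invert(pts_net[1])
    return left, right


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def _affine_params(angle_deg: float, scale: float, shape):
    """Forward map p' = c + s R (p - c) about the image center (x, y order)."""
    h, w = shape
    c = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    t = np.deg2rad(angle_deg)
    R = scale * np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])
    offset = c - R @ c
    return R, offset


def augment(sample: Sample, rng: np.random.Generator,
            rotation_range=(-30.0, 30.0), scale_range=(0.9, 1.1),
            sigma: float = DEFAULT_SIGMA, max_retries: int = 10) -> Sample:
    """Random rotation/scale applied identically to image, mask and endpoints.

    If the transformed endpoints repeatedly leave the frame, the sample is
    returned unaugmented.
    """
    h, w = sample.image.shape
    for _ in range(max_retries):
        angle = rng.uniform(*rotation_range)
        scale = rng.uniform(*scale_range)
        R, offset = _affine_params(angle, scale, (h, w))
        if sample.endpoints is not None:
            new_pts = [tuple(R @ np.asarray(p) + offset) for p in sample.endpoints]
            ok = all(0 <= x <= w - 1 and 0 <= y <= h - 1 for x, y in new_pts)
            if not ok:
                continue
        else:
            new_pts = None
        # scipy's affine_transform maps output->input, so invert; its matrix
        # acts on (row, col) = (y, x)
        Rinv = np.linalg.inv(R)
        Ryx = Rinv[::-1, ::-1]  # swap x/y axes
        off_yx = -Ryx @ offset[::-1]
        image = ndimage.affine_transform(sample.image, Ryx, offset=off_yx,
                                         order=1, mode="constant", cval=-1.0)
        mask = ndimage.affine_transform(sample.mask, Ryx, offset=off_yx,
                                        order=0, mode="constant", cval=0)
        heatmaps = (make_heatmaps(new_pts, (h, w), sigma) if new_pts is not None
                    else np.zeros_like(sample.heatmaps))
        record = dict(sample.transform_record, rotation_deg=float(angle),
                      scale=float(scale))
        return replace(sample, image=image.astype(np.float32), mask=mask,
                       heatmaps=heatmaps,
                       endpoints=tuple(new_pts) if new_pts is not None else None,
                       transform_record=record)
    return sample


# ---------------------------------------------------------------------------
# manifest handling and patient-wise split
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = ["image_path", "mask_path", "patient_id", "is_standard",
                    "xl", "yl", "xr", "yr", "aop_true"]


def load_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    return df


def split_by_patient(manifest: pd.DataFrame, ratios=(5, 2, 3), seed: int = 0) -> SplitPlan:
    """Patient-disjoint split approximating per-stratum image-count ratios.

    Patients are shuffled with ``seed`` and greedily assigned to the set that
    minimizes the squared deviation of per-stratum image counts from the
    ratio targets.
    """
    patients = sorted(manifest["patient_id"].unique())
    if len(patients) < 3:
        raise ValueError("need at least 3 patients")
    frac = np.asarray(ratios, float) / float(sum(ratios))
    # per-patient (standard, nonstandard) image counts
    counts = {p: np.array([
        int(((manifest.patient_id == p) & (manifest.is_standard)).sum()),
        int(((manifest.patient_id == p) & (~manifest.is_standard.astype(bool))).sum()),
    ]) for p in patients}
    totals = np.sum(list(counts.values()), axis=0)
    targets = np.outer(frac, totals)            # (3 sets, 2 strata)
    rng = np.random.default_rng(seed)
    order = [patients[i] for i in rng.permutation(len(patients))]
    assigned = np.zeros((3, 2))
    sets: list[list] = [[], [], []]
    for p in order:
        errs = []
        for s in range(3):
            trial = assigned.copy()
            trial[s] += counts[p]
            errs.append(float(((trial - targets) ** 2).sum()))
        s = int(np.argmin(errs))
        assigned[s] += counts[p]
        sets[s].append(p)
    return SplitPlan(train_ids=tuple(sorted(sets[0])),
                     val_ids=tuple(sorted(sets[1])),
                     test_ids=tuple(sorted(sets[2])),
                     ratios=tuple(ratios))


def load_samples(manifest: pd.DataFrame, root, target_size=DEFAULT_TARGET_SIZE,
                 sigma: float = DEFAULT_SIGMA) -> list[Sample]:
    """Materialize network-ready samples for the manifest rows.

    Reads 8-bit grayscale images (PNG or BMP) and indexed masks, resizes to
    ``target_size``, maps endpoints through the scale map and builds heatmaps.
    Nonstandard rows get zero heatmaps and ``endpoints=None``.
    """
    from pathlib import Path
    root = Path(root)
    out = []
    for _, row in manifest.iterrows():
        raw = np.asarray(Image.open(root / row.image_path).convert("L"))
        image, smap = preprocess(raw, target_size)
        mask_raw = np.asarray(Image.open(root / row.mask_path)).astype(np.uint8)
        if mask_raw.shape != image.shape:
            mask = _sk_resize(mask_raw, image.shape, order=0,
                              preserve_range=True, anti_aliasing=False).astype(np.uint8)
        else:
            mask = mask_raw
        standard = bool(row.is_standard)
        if standard and np.isfinite(row.xl):
            left = smap.apply((row.xl, row.yl))
            right = smap.apply((row.xr, row.yr))
            endpoints = (left, right)
            heatmaps = make_heatmaps(endpoints, image.shape, sigma)
        else:
            endpoints = None
            heatmaps = np.zeros((3,) + image.shape, dtype=np.float32)
        out.append(Sample(image=image, mask=mask, heatmaps=heatmaps,
                          class_label=int(standard), endpoints=endpoints,
                          spatial_map=smap, transform_record={},
                          patient_id=str(row.patient_id),
                          aop_true=float(row.aop_true),
                          image_path=str(row.image_path)))
    return out


def samples_from_phantoms(samples, target_size=None, sigma: float = DEFAULT_SIGMA) -> list[Sample]:
    """Network-ready samples directly from in-memory phantom samples."""
    out = []
    for ps in samples:
        target = target_size or ps.image.shape
        image, smap = preprocess(ps.image, target)
        mask = ps.mask
        if mask.shape != image.shape:
            mask = _sk_resize(mask, image.shape, order=0, preserve_range=True,
                              anti_aliasing=False).astype(np.uint8)
        if ps.is_standard:
            endpoints = (smap.apply(ps.left_endpoint), smap.apply(ps.right_endpoint))
            heatmaps = make_heatmaps(endpoints, image.shape, sigma)
        else:
            endpoints = None
            heatmaps = np.zeros((3,) + image.shape, dtype=np.float32)
        out.append(Sample(image=image, mask=mask, heatmaps=heatmaps,
                          class_label=int(ps.is_standard), endpoints=endpoints,
                          spatial_map=smap, transform_record={},
                          patient_id=ps.patient_id, aop_true=ps.aop_true))
    return out
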