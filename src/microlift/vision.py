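"""Dish imaging: synthetic image generation, detection, filtering,
camera-to-stage calibration, and pick verification.

The platform images a back-illuminated culture dish, so microtissues appear
as dark blobs on a bright background. Detection is classical: threshold the
inverted image (Otsu by default), label connected components, and measure
each component's intensity-weighted centroid and area. The equivalent
diameter is derived from a subpixel area estimate — the summed darkness
fraction over the component, which for an anti-aliased blob recovers the
true covered area well below one pixel of quantization — rather than from
the binary pixel count.

Conventions: image origin top-left, x right / y down, 0-based pixel
coordinates; dish coordinates in mm are pixel coordinates times the pixel
pitch. The robot stage plane uses mm with y up; the affine calibration
absorbs the axis flip.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import cKDTree
from skimage import filters, measure

from . import units

BACKGROUND_LEVEL = 200.0
FOREGROUND_LEVEL = 60.0


@dataclass(frozen=True)
class DishImage:
    """Grayscale dish image with its spatial calibration."""

    pixels: np.ndarray  # 2-D float array, intensities in [0, 255]
    pixel_pitch_um: float
    tag: str = ""

    def __post_init__(self) -> None:
        if self.pixels.ndim != 2:
            raise ValueError("dish image must be 2-D grayscale")
        if self.pixel_pitch_um <= 0:
            raise ValueError("pixel pitch must be positive")

    def px_to_mm(self, x_px: float, y_px: float) -> tuple[float, float]:
        # pixel i spans [i, i+1) in grid units; its center sits at i + 0.5
        s = self.pixel_pitch_um / 1000.0
        return (x_px + 0.5) * s, (y_px + 0.5) * s


@dataclass(frozen=True)
class GroundTruthBlob:
    x_mm: float
    y_mm: float
    diameter_um: float
    adhered_pair: bool = False


@dataclass(frozen=True)
class GroundTruth:
    """Blob positions/sizes driving the synthetic generator."""

    blobs: tuple[GroundTruthBlob, ...]
    dish_width_mm: float
    dish_height_mm: float

    def __post_init__(self) -> None:
        for b in self.blobs:
            r = b.diameter_um / 2000.0
            if not (r <= b.x_mm <= self.dish_width_mm - r
                    and r <= b.y_mm <= self.dish_height_mm - r):
                raise ValueError("blob outside the dish footprint")


def random_ground_truth(
    n_blobs: int,
    dish_width_mm: float = 12.0,
    dish_height_mm: float = 12.0,
    diameter_um: float | tuple[float, float] = 400.0,
    min_separation_mm: float = 2.5,
    seed: int = 0,
) -> GroundTruth:
    """Place n non-overlapping blobs by rejection sampling (seeded)."""
    rng = np.random.default_rng(seed)
    lo, hi = (diameter_um, diameter_um) if np.isscalar(diameter_um) else diameter_um
    pts: list[tuple[float, float]] = []
    blobs: list[GroundTruthBlob] = []
    margin = hi / 2000.0 + 0.1
    for _ in range(20000):
        if len(blobs) == n_blobs:
            break
        x = rng.uniform(margin, dish_width_mm - margin)
        y = rng.uniform(margin, dish_height_mm - margin)
        if pts and np.min(np.hypot(np.array(pts)[:, 0] - x,
                                   np.array(pts)[:, 1] - y)) < min_separation_mm:
            continue
        d = float(rng.uniform(lo, hi))
        pts.append((x, y))
        blobs.append(GroundTruthBlob(x, y, d))
    if len(blobs) < n_blobs:
        raise ValueError("could not place all blobs; lower n or separation")
    return GroundTruth(tuple(blobs), dish_width_mm, dish_height_mm)


def generate_dish_image(
    truth: GroundTruth,
    pixel_pitch_um: float = 10.0,
    noise_sd: float = 3.0,
    seed: int = 0,
    background: float = BACKGROUND_LEVEL,
    foreground: float = FOREGROUND_LEVEL,
    tag: str = "synthetic",
) -> DishImage:
    """Render a bright-field dish: dark anti-aliased disks on a bright
    background plus additive Gaussian noise. Deterministic for a fixed seed.

    Overlapping blobs are rendered merged (coverage is combined with a max),
    emulating adhered pairs; whether a blob belongs to a pair is carried in
    the ground truth, not the image.
    """
    scale = pixel_pitch_um / 1000.0  # mm per px
    ny = int(round(truth.dish_height_mm / scale))
    nx = int(round(truth.dish_width_mm / scale))
    coverage = np.zeros((ny, nx))
    yy = np.arange(ny) + 0.5
    xx = np.arange(nx) + 0.5
    for b in truth.blobs:
        r_px = b.diameter_um / (2.0 * pixel_pitch_um)
        cx = b.x_mm / scale
        cy = b.y_mm / scale
        x0, x1 = int(max(0, cx - r_px - 2)), int(min(nx, cx + r_px + 3))
        y0, y1 = int(max(0, cy - r_px - 2)), int(min(ny, cy + r_px + 3))
        dist = np.hypot(xx[None, x0:x1] - cx, yy[y0:y1, None] - cy)
        # pixel coverage approximated by the signed distance to the rim
        cov = np.clip(r_px + 0.5 - dist, 0.0, 1.0)
        np.maximum(coverage[y0:y1, x0:x1], cov, out=coverage[y0:y1, x0:x1])
    img = background - (background - foreground) * coverage
    if noise_sd > 0:
        img = img + np.random.default_rng(seed).normal(0.0, noise_sd, img.shape)
    return DishImage(img, pixel_pitch_um, tag=tag)


@dataclass
class Detection:
    """One segmented microtissue and its geometry."""

    id: int
    x_px: float
    y_px: float
    x_mm: float
    y_mm: float
    area_px2: float  # subpixel (coverage-weighted) area
    diameter_um: float
    nn_mm: float = math.inf
    flags: set[str] = field(default_factory=set)


def detect_microtissues(
    image: DishImage,
    min_area_px2: float = 40.0,
    max_area_px2: float | None = None,
    threshold: float | str = "otsu",
) -> list[Detection]:
    """Segment dark blobs and measure them.

    threshold="otsu" picks the split automatically on the inverted image; a
    float gives a fixed intensity cut (pixels darker than it are foreground).
    A blank or saturated image yields an empty list with a warning.
    """
    img = np.asarray(image.pixels, dtype=float)
    if threshold == "otsu":
        if float(img.max() - img.min()) < 1e-9:
            warnings.warn("image has no contrast; returning no detections")
            return []
        cut = filters.threshold_otsu(img)
        # guard against splitting pure noise: the cut must sit well below
        # the background, measured in background-noise units
        above = img[img >= cut]
        if above.size == 0 or float(np.median(above)) - cut < 6.0 * max(
                float(above.std()), 1e-9):
            warnings.warn("no significant dark blobs; returning no detections")
            return []
    else:
        cut = float(threshold)
    mask = img < cut
    if not mask.any():
        warnings.warn("no pixels below threshold; returning no detections")
        return []
    labels = measure.label(mask, connectivity=2)
    background = float(np.median(img[~mask])) if (~mask).any() else BACKGROUND_LEVEL
    dets: list[Detection] = []
    pad = 3
    for region in measure.regionprops(labels, intensity_image=img):
        if region.area < min_area_px2:
            continue
        if max_area_px2 is not None and region.area > max_area_px2:
            continue
        by0, bx0, by1, bx1 = region.bbox
        y0, x0 = max(by0 - pad, 0), max(bx0 - pad, 0)
        y1, x1 = min(by1 + pad, img.shape[0]), min(bx1 + pad, img.shape[1])
        patch = img[y0:y1, x0:x1]
        inmask = labels[y0:y1, x0:x1] == region.label
        # foreground from the blob core (noise averages out); the dilated
        # mask picks up the anti-aliased rim the threshold cut in half
        core = ndi.binary_erosion(inmask, iterations=2)
        foreground = float(patch[core].mean() if core.any() else patch[inmask].min())
        depth = background - foreground
        if depth <= 0:
            continue
        support = ndi.binary_dilation(inmask, iterations=2)
        lbl_patch = labels[y0:y1, x0:x1]
        support &= (lbl_patch == region.label) | (lbl_patch == 0)
        darkness = np.clip((background - patch) / depth, 0.0, 1.0) * support
        area_sub = float(darkness.sum())
        total = darkness.sum()
        cy = float((darkness * np.arange(y0, y1)[:, None]).sum() / total)
        cx = float((darkness * np.arange(x0, x1)[None, :]).sum() / total)
        diam_um = 2.0 * math.sqrt(area_sub / math.pi) * image.pixel_pitch_um
        flags: set[str] = set()
        # bubbles image as bright-cored rings: flag if the blob center is
        # nearly as bright as the background
        ry, rx = int(round(cy - y0)), int(round(cx - x0))
        if 0 <= ry < patch.shape[0] and 0 <= rx < patch.shape[1]:
            if patch[ry, rx] > background - 0.25 * depth and inmask[ry, rx]:
                flags.add("suspected_bubble_or_debris")
        x_mm, y_mm = image.px_to_mm(cx, cy)
        dets.append(
            Detection(0, cx, cy, x_mm, y_mm, area_sub, diam_um, flags=flags)
        )
    dets.sort(key=lambda d: (d.y_px, d.x_px))
    for i, d in enumerate(dets):
        d.id = i
    annotate_nearest_neighbors(dets)
    return dets


def annotate_nearest_neighbors(detections: list[Detection]) -> None:
    """Fill each detection's nearest-neighbor distance (mm) in place."""
    if len(detections) < 2:
        for d in detections:
            d.nn_mm = math.inf
        return
    pts = np.array([(d.x_mm, d.y_mm) for d in detections])
    dist, _ = cKDTree(pts).query(pts, k=2)
    for d, nn in zip(detections, dist[:, 1]):
        d.nn_mm = float(nn)


def filter_candidates(
    detections: list[Detection],
    size_range_um: tuple[float, float],
    min_nn_mm: float = 2.0,
    exclude_flags: tuple[str, ...] = ("suspected_bubble_or_debris",),
) -> list[Detection]:
    """Pickable subset: in the size window, isolated by ≥ min_nn_mm, and
    free of exclusion flags. Preserves scan order."""
    lo, hi = size_range_um
    out = []
    for d in detections:
        if not (lo <= d.diameter_um <= hi):
            continue
        if d.nn_mm < min_nn_mm:
            continue
        if any(f in d.flags for f in exclude_flags):
            continue
        out.append(d)
    return out


@dataclass(frozen=True)
class AffineCalibration:
    """Least-squares affine map from camera pixels to stage millimetres."""

    matrix: np.ndarray  # 2x2
    translation: np.ndarray  # (2,)
    residual_rms_mm: float

    def __post_init__(self) -> None:
        if abs(np.linalg.det(self.matrix)) < 1e-15:
            raise ValueError("affine linear part is singular")

    def apply(self, points_px: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points_px, dtype=float))
        return pts @ self.matrix.T + self.translation


def calibrate_transform(
    camera_points_px: np.ndarray, robot_points_mm: np.ndarray
) -> AffineCalibration:
    """Fit camera→stage affine from ≥3 non-collinear correspondences.

    In practice the correspondences come from driving the stage through
    known positions while the camera tracks a laser dot.
    """
    cam = np.asarray(camera_points_px, dtype=float)
    rob = np.asarray(robot_points_mm, dtype=float)
    if cam.shape != rob.shape or cam.ndim != 2 or cam.shape[1] != 2:
        raise ValueError("need matched (n, 2) point arrays")
    if cam.shape[0] < 3:
        raise ValueError("need at least 3 correspondences")
    centered = cam - cam.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9 * max(1.0, np.abs(centered).max())) < 2:
        raise ValueError("correspondences are collinear")
    design = np.hstack([cam, np.ones((cam.shape[0], 1))])
    coef, *_ = np.linalg.lstsq(design, rob, rcond=None)
    matrix = coef[:2].T
    translation = coef[2]
    resid = design @ coef - rob
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return AffineCalibration(matrix=matrix, translation=translation, residual_rms_mm=rms)


def verify_pick(
    before: DishImage,
    after: DishImage,
    target: Detection,
    match_radius_mm: float = 0.5,
    **detect_kwargs,
) -> str:
    """Before/after comparison at the target position.

    Returns "picked" if no blob is re-detected within match_radius_mm of the
    target's centroid in the after image, else "still_present" (the tissue
    was not lifted, or moved less than the radius — either way a retry)."""
    if before.pixels.shape != after.pixels.shape:
        raise ValueError("before/after images must share geometry")
    if before.pixel_pitch_um != after.pixel_pitch_um:
        raise ValueError("before/after images must share pixel pitch")
    for d in detect_microtissues(after, **detect_kwargs):
        if math.hypot(d.x_mm - target.x_mm, d.y_mm - target.y_mm) <= match_radius_mm:
            return "still_present"
    return "picked"


# --- tabular IO -----------------------------------------------------------

DETECTION_COLUMNS = [
    "id", "x_px", "y_px", "x_mm", "y_mm", "area_px2", "diameter_um", "nn_mm", "flags",
]


def detections_to_frame(detections: list[Detection]) -> pd.DataFrame:
    rows = [
        {
            "id": d.id,
            "x_px": d.x_px,
            "y_px": d.y_px,
            "x_mm": d.x_mm,
            "y_mm": d.y_mm,
            "area_px2": d.area_px2,
            "diameter_um": d.diameter_um,
            "nn_mm": d.nn_mm,
            "flags": ";".join(sorted(d.flags)),
        }
        for d in detections
    ]
    return pd.DataFrame(rows, columns=DETECTION_COLUMNS)


def frame_to_detections(df: pd.DataFrame) -> list[Detection]:
    out = []
    for row in df.itertuples(index=False):
        flags = set(str(row.flags).split(";")) - {"", "nan"} if pd.notna(row.flags) else set()
        out.append(
            Detection(
                int(row.id), float(row.x_px), float(row.y_px), float(row.x_mm),
                float(row.y_mm), float(row.area_px2), float(row.diameter_um),
                float(row.nn_mm) if pd.notna(row.nn_mm) else math.inf, flags,
            )
        )
    return out
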