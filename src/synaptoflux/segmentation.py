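"""Puncta ROI detection.

The pipeline mirrors common practice for synaptic-bouton quantification:
background statistics are pooled from rectangular cell-free regions (at least
three per field of view), the common threshold is the pooled mean plus two
standard deviations, the binary mask is split by marker-controlled watershed,
and particles are kept only if their area-equivalent diameter falls within
0.3-3 um -- the size window of synaptic boutons (~1 um).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.measure import regionprops
from skimage.segmentation import watershed as _watershed

from .errors import ValidationError
from .types import ImageStack

logger = logging.getLogger("synaptoflux")

#: (row, col, height, width) rectangle in pixel coordinates, 0-based.
Rect = tuple[int, int, int, int]


@dataclass(frozen=True)
class BackgroundModel:
    """Pooled background statistics; threshold = mean + 2*sd."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValidationError("background sd must be >= 0")

    @property
    def threshold(self) -> float:
        return self.mean + 2.0 * self.sd


@dataclass
class RoiSet:
    """Labeled regions plus a per-ROI record table.

    ``labels`` maps each pixel to an ROI id (0 = background); ``table`` has
    one row per ROI with area (px and um^2), area-equivalent diameter (um)
    and centroid (row, col).
    """

    labels: np.ndarray
    table: pd.DataFrame
    pixel_size: float

    @property
    def ids(self) -> np.ndarray:
        return self.table["id"].to_numpy()

    def pixels(self, roi_id: int) -> tuple[np.ndarray, np.ndarray]:
        """(rows, cols) arrays of the pixels belonging to one ROI."""
        return np.nonzero(self.labels == roi_id)

    def __len__(self) -> int:
        return len(self.table)


def _first_frame(image: ImageStack | np.ndarray) -> np.ndarray:
    if isinstance(image, ImageStack):
        return image.data[0]
    img = np.asarray(image, dtype=np.float64)
    return img[0] if img.ndim == 3 else img


def estimate_background(
    images: list[ImageStack | np.ndarray],
    cellfree_rois: list[list[Rect]],
    pool_across_conditions: bool = True,
) -> BackgroundModel | list[BackgroundModel]:
    """Background model from rectangular cell-free regions.

    Each FOV contributes at least three rectangles; all rectangle pixels are
    pooled (regardless of condition when ``pool_across_conditions``) and the
    common threshold is ``mean + 2*sd``.  With pooling disabled a per-FOV
    list of models is returned instead.
    """
    if len(images) != len(cellfree_rois):
        raise ValidationError("one rectangle list per image is required")
    per_fov: list[np.ndarray] = []
    for img, rects in zip(images, cellfree_rois):
        frame = _first_frame(img)
        if len(rects) < 3:
            raise ValidationError(
                f"each FOV needs >= 3 cell-free rectangles, got {len(rects)}"
            )
        pix = []
        for r0, c0, h, w in rects:
            if r0 < 0 or c0 < 0 or r0 + h > frame.shape[0] or c0 + w > frame.shape[1]:
                raise ValidationError(f"rectangle {(r0, c0, h, w)} lies outside its image")
            pix.append(frame[r0 : r0 + h, c0 : c0 + w].ravel())
        per_fov.append(np.concatenate(pix))
    if pool_across_conditions:
        pooled = np.concatenate(per_fov)
        model = BackgroundModel(float(pooled.mean()), float(pooled.std()))
        logger.info(
            "background: %d px pooled, mean=%.2f sd=%.2f threshold=%.2f",
            pooled.size, model.mean, model.sd, model.threshold,
        )
        return model
    return [BackgroundModel(float(p.mean()), float(p.std())) for p in per_fov]


def threshold_mask(image: ImageStack | np.ndarray, threshold: float) -> np.ndarray:
    """Binary mask of pixels strictly above the threshold."""
    if not np.isfinite(threshold):
        raise ValidationError("threshold must be finite")
    return _first_frame(image) > threshold


def split_watershed(
    mask: np.ndarray,
    intensity_image: ImageStack | np.ndarray,
    min_distance_px: int = 5,
    smoothing_sigma: float = 1.0,
) -> np.ndarray:
    """Split touching puncta with marker-controlled watershed.

    Markers are intensity peaks (lightly smoothed, minimum separation
    ``min_distance_px``) inside the mask; the watershed floods the inverted
    intensity with 8-connectivity.  Mask components without any detected peak
    keep a single label, so every mask pixel receives exactly one label.
    """
    img = _first_frame(intensity_image)
    if mask.shape != img.shape:
        raise ValidationError("mask and intensity image must share a shape")
    if not mask.any():
        return np.zeros(mask.shape, dtype=np.int32)
    smoothed = ndi.gaussian_filter(img, smoothing_sigma)
    peaks = peak_local_max(
        np.where(mask, smoothed, smoothed.min()),
        min_distance=min_distance_px,
        labels=mask.astype(np.int32),
        exclude_border=False,
    )
    markers = np.zeros(mask.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    labels = _watershed(-smoothed, markers, mask=mask, connectivity=2)
    # components that contained no peak (e.g. flat plateaus) stay unlabeled;
    # give each its own label
    leftover = mask & (labels == 0)
    if leftover.any():
        extra, n_extra = ndi.label(leftover, structure=np.ones((3, 3), dtype=int))
        labels = labels + np.where(extra > 0, extra + labels.max(), 0)
        logger.info("watershed: %d peak-free components labeled whole", n_extra)
    return labels.astype(np.int32)


def filter_particles(
    labels: np.ndarray,
    pixel_size: float,
    min_diameter: float = 0.3,
    max_diameter: float = 3.0,
) -> RoiSet:
    """Keep ROIs whose area-equivalent diameter lies in [min, max] um.

    The equivalent diameter of an ROI of area A is ``sqrt(4*A/pi)``; bounds
    are inclusive.  Dropped particles are counted in the log.  The operation
    is idempotent: filtering an already-filtered label map changes nothing.
    """
    if pixel_size <= 0:
        raise ValidationError("pixel_size must be > 0")
    labels = np.asarray(labels)
    records = []
    dropped = 0
    for prop in regionprops(labels):
        area_um2 = prop.area * pixel_size**2
        equiv_d = float(np.sqrt(4.0 * area_um2 / np.pi))
        if min_diameter <= equiv_d <= max_diameter:
            records.append(
                {
                    "old_label": prop.label,
                    "area_px": int(prop.area),
                    "area_um2": area_um2,
                    "equiv_diameter_um": equiv_d,
                    "centroid_row": prop.centroid[0],
                    "centroid_col": prop.centroid[1],
                }
            )
        else:
            dropped += 1
    logger.info("filter_particles: kept %d ROIs, dropped %d", len(records), dropped)
    out = np.zeros_like(labels, dtype=np.int32)
    table_rows = []
    for new_id, rec in enumerate(records, start=1):
        out[labels == rec["old_label"]] = new_id
        row = {k: v for k, v in rec.items() if k != "old_label"}
        row["id"] = new_id
        table_rows.append(row)
    table = pd.DataFrame(
        table_rows,
        columns=["id", "area_px", "area_um2", "equiv_diameter_um", "centroid_row", "centroid_col"],
    )
    return RoiSet(out, table, pixel_size)


def intersect_masks(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Logical AND of two binary masks (e.g. marker+ AND cell+)."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValidationError(f"mask shapes differ: {a.shape} vs {b.shape}")
    return a & b


def segment_scene(
    image: ImageStack | np.ndarray,
    background: BackgroundModel,
    pixel_size: float | None = None,
    min_diameter: float = 0.3,
    max_diameter: float = 3.0,
    min_distance_px: int = 5,
) -> RoiSet:
    """Threshold -> watershed -> size filter, the standard puncta pipeline."""
    if pixel_size is None:
        if not isinstance(image, ImageStack):
            raise ValidationError("pixel_size required when image is a bare array")
        pixel_size = image.pixel_size
    mask = threshold_mask(image, background.threshold)
    labels = split_watershed(mask, image, min_distance_px=min_distance_px)
    return filter_particles(labels, pixel_size, min_diameter, max_diameter)
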