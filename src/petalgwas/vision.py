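"""Petal segmentation and shape descriptors from single-petal photographs.

The segmentation pipeline follows the classic gradient-based recipe: a Sobel
gradient magnitude is thresholded into a binary edge mask, the edge mask is
dilated with two perpendicular linear structuring elements to close small gaps
in the outline, and interior holes are filled. Measurements are expressed in
centimetres via a 1-cm white reference disk present in every frame.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import color, filters, measure, morphology

from .datatypes import PetalMeasure

logger = logging.getLogger(__name__)

PETAL_TYPES = ("standard", "vexil", "wing", "keel")

# descriptors fed to downstream trait tables by default; `ratio` is derivable
# from the two lengths and is computed but not selected
DEFAULT_DESCRIPTOR_SELECTION = (
    "major_length_cm",
    "minor_length_cm",
    "area_cm2",
    "perimeter_cm",
    "eccentricity",
    "circularity",
)


@dataclass(frozen=True)
class ScaleCal:
    """Pixels-per-centimetre calibration from the reference disk."""

    pixels_per_cm: float

    def __post_init__(self) -> None:
        if not self.pixels_per_cm > 0:
            raise ValueError("pixels_per_cm must be positive")


def _to_gray(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image, dtype=float)
    if img.ndim == 3:
        img = color.rgb2gray(img)
    if img.ndim != 2:
        raise ValueError(f"expected 2-D or RGB image, got shape {image.shape}")
    return img


def gradient_mask(image: np.ndarray, threshold_scale: float = 1.0) -> np.ndarray:
    """Binary edge mask from a thresholded Sobel gradient magnitude.

    The base threshold is estimated automatically (Otsu on the gradient
    magnitude) and multiplied by ``threshold_scale``. A constant image yields
    an empty mask with a warning rather than an error.
    """
    if threshold_scale <= 0:
        raise ValueError("threshold_scale must be > 0")
    img = _to_gray(image)
    grad = filters.sobel(img)
    if grad.max() <= 0:
        logger.warning("gradient_mask: constant image, returning empty mask")
        return np.zeros(img.shape, dtype=bool)
    base = filters.threshold_otsu(grad)
    return grad > threshold_scale * base


def _line_elements(line_length: int) -> tuple[np.ndarray, np.ndarray]:
    if line_length < 3 or line_length % 2 == 0:
        raise ValueError("line_length must be odd and >= 3")
    return np.ones((line_length, 1), dtype=bool), np.ones((1, line_length), dtype=bool)


def dilate_directional(mask: np.ndarray, line_length: int = 3) -> np.ndarray:
    """Dilate sequentially with a vertical then a horizontal line element."""
    vert, horiz = _line_elements(line_length)
    mask = np.asarray(mask, dtype=bool)
    return ndimage.binary_dilation(
        ndimage.binary_dilation(mask, vert), horiz
    )


def erode_directional(mask: np.ndarray, line_length: int = 3) -> np.ndarray:
    """Inverse smoothing step: erode with the same two perpendicular lines."""
    vert, horiz = _line_elements(line_length)
    mask = np.asarray(mask, dtype=bool)
    return ndimage.binary_erosion(
        ndimage.binary_erosion(mask, vert), horiz
    )


def fill_holes(mask: np.ndarray) -> np.ndarray:
    """Fill interior background components not connected to the border."""
    return ndimage.binary_fill_holes(np.asarray(mask, dtype=bool))


def detect_reference_disk(
    image: np.ndarray,
    expected_diameter_cm: float = 1.0,
    min_circularity: float = 0.9,
    min_area_px: int = 200,
    max_area_frac: float = 0.25,
) -> tuple[ScaleCal, np.ndarray]:
    """Locate the single bright near-circular reference disk and calibrate.

    The brightest intensity class (3-class Otsu) is binarized; candidate
    regions must satisfy the circularity and size bounds. Exactly one
    candidate must remain; zero or several raise ``ValueError`` listing what
    was found. ``pixels_per_cm`` is the region's equivalent diameter divided
    by the expected physical diameter.
    """
    img = _to_gray(image)
    try:
        cuts = filters.threshold_multiotsu(img, classes=3)
        bright = img > cuts[-1]
    except ValueError:  # fewer than 3 grey levels
        bright = img > filters.threshold_otsu(img)
    labels = measure.label(bright)
    max_area = max_area_frac * img.size

    candidates = []
    for region in measure.regionprops(labels):
        if not (min_area_px <= region.area <= max_area):
            continue
        perim = region.perimeter_crofton
        if perim <= 0:
            continue
        circ = 4 * math.pi * region.area / perim**2
        if circ >= min_circularity:
            candidates.append((region, circ))

    if len(candidates) != 1:
        desc = [
            f"label={r.label} area={r.area} centroid={tuple(round(c) for c in r.centroid)} "
            f"circularity={circ:.3f}"
            for r, circ in candidates
        ]
        raise ValueError(
            f"expected exactly one reference disk, found {len(candidates)}: {desc}"
        )
    region, _ = candidates[0]
    px_per_cm = region.equivalent_diameter_area / expected_diameter_cm
    disk_mask = labels == region.label
    return ScaleCal(pixels_per_cm=px_per_cm), disk_mask


def measure_region(mask: np.ndarray, scale: ScaleCal) -> PetalMeasure:
    """Shape descriptors of the single foreground region, in cm units.

    Area is the pixel count / scale^2; perimeter uses the Crofton contour
    estimator (so a rasterized circle's circularity approaches 1); lengths
    and eccentricity come from the ellipse-equivalent second central moments.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    labels = measure.label(mask)
    regions = measure.regionprops(labels)
    if len(regions) > 1:
        regions = sorted(regions, key=lambda r: r.area, reverse=True)
        logger.warning(
            "measure_region: %d components, measuring the largest", len(regions)
        )
    region = regions[0]
    s = scale.pixels_per_cm
    area = region.area / s**2
    perim = region.perimeter_crofton / s
    major = region.axis_major_length / s
    minor = region.axis_minor_length / s
    ratio = minor / major if major > 0 else 1.0
    return PetalMeasure(
        major_length_cm=major,
        minor_length_cm=minor,
        area_cm2=area,
        perimeter_cm=perim,
        eccentricity=region.eccentricity,
        ratio=ratio,
        circularity=4 * math.pi * area / perim**2 if perim > 0 else float("nan"),
    )


def segment_petal(
    image: np.ndarray,
    threshold_scale: float = 1.0,
    line_length: int = 3,
    smooth_iterations: int = 2,
) -> tuple[np.ndarray, ScaleCal]:
    """Full single-frame pipeline: calibrate, then gradient-dilate-fill.

    Returns the petal mask (largest non-disk component) and the calibration.
    ``smooth_iterations`` erosions with the same two line elements used for
    dilation are applied after hole filling, undoing the outward bias that
    the edge mask plus dilation put on the outline (0 disables smoothing).
    """
    scale, disk_mask = detect_reference_disk(image)
    edges = gradient_mask(image, threshold_scale=threshold_scale)
    dilated = dilate_directional(edges, line_length=line_length)
    filled = fill_holes(dilated)
    for _ in range(smooth_iterations):
        filled = erode_directional(filled, line_length=line_length)

    # drop the disk (and anything overlapping its dilated footprint)
    disk_grown = ndimage.binary_dilation(disk_mask, morphology.disk(line_length + 2))
    labels = measure.label(filled)
    best_label, best_area = 0, 0
    for region in measure.regionprops(labels):
        if disk_grown[labels == region.label].any():
            continue
        if region.area > best_area:
            best_label, best_area = region.label, region.area
    if best_label == 0:
        raise ValueError("segmentation found no petal component distinct from the disk")
    return labels == best_label, scale


def measure_petal_image(image: np.ndarray, **kwargs) -> PetalMeasure:
    """Convenience wrapper: segment one frame and measure the petal."""
    mask, scale = segment_petal(image, **kwargs)
    return measure_region(mask, scale)


def extract_petal_phenotypes(
    manifest: pd.DataFrame,
    images: dict[str, np.ndarray] | None = None,
    descriptors: Sequence[str] = DEFAULT_DESCRIPTOR_SELECTION,
    threshold_scale: float = 1.0,
    line_length: int = 3,
) -> pd.DataFrame:
    """Run the pipeline over a batch of frames and build the trait table.

    ``manifest`` needs columns path, sample, petal_type; ``images`` may map
    paths to in-memory arrays (otherwise frames are read from disk). Wing and
    keel replicates are averaged per sample. Output columns are named
    ``<type>_<descriptor>``; frames whose segmentation fails are logged and
    leave that cell missing.
    """
    required = {"path", "sample", "petal_type"}
    if not required.issubset(manifest.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    bad_types = set(manifest["petal_type"]) - set(PETAL_TYPES)
    if bad_types:
        raise ValueError(f"unknown petal types in manifest: {sorted(bad_types)}")

    records = []
    for row in manifest.itertuples(index=False):
        if images is not None and row.path in images:
            img = images[row.path]
        else:
            from imageio.v3 import imread

            img = imread(Path(row.path))
        try:
            pm = measure_petal_image(
                img, threshold_scale=threshold_scale, line_length=line_length
            )
        except ValueError as exc:
            logger.warning(
                "segmentation failed for %s (%s/%s): %s",
                row.path, row.sample, row.petal_type, exc,
            )
            continue
        rec = {"sample": row.sample, "petal_type": row.petal_type}
        rec.update(pm.as_dict())
        records.append(rec)

    long = pd.DataFrame(records)
    if long.empty:
        return pd.DataFrame(index=pd.Index([], name="sample"))
    mean = long.groupby(["sample", "petal_type"])[list(descriptors)].mean()
    wide = mean.unstack("petal_type")
    wide.columns = [f"{ptype}_{desc}" for desc, ptype in wide.columns]
    return wide.sort_index(axis=1)
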