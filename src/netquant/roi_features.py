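"""Per-ROI geometric and intensity features.

Each segmented DNA object (nominally one neutrophil) is summarised by the
seven features the downstream caller consumes: area, raw integrated
density (the sum of member-pixel intensities, a proxy for DNA content),
aspect ratio and roundness of the fitted ellipse, solidity, and the
minimum and maximum member brightness.

Roundness is 4 * area / (pi * major_axis**2) with the major axis from the
second central moments of the pixel set — the ImageJ definition, noted
explicitly because "roundness" has competing formulas. Tiny discrete
regions may exceed 1.0 by a small discretisation epsilon.

Solidity divides the pixel area by the area of the convex hull of the
region treated as a union of unit pixel squares (the hull of all pixel
corners). That convention makes a filled convex square have solidity
exactly 1 and guarantees solidity <= 1 for every region, which a hull over
pixel *centres* would not.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from skimage import measure

from .image_io import ImageField
from .segmentation import LabelMap


@dataclass
class RoiMeasurement:
    """Feature vector of one segmented nuclear object."""

    roi_id: int
    slide_id: str
    condition: str
    field_index: int
    area_px: int
    raw_integrated_density: float
    aspect_ratio: float
    roundness: float
    solidity: float
    min_brightness: float
    max_brightness: float
    touches_border: bool
    centroid: tuple[float, float]


def convex_hull_area(pixel_coords: np.ndarray) -> float:
    """Area of the convex hull of a pixel set taken as unit squares.

    ``pixel_coords`` is an (N, 2) array of (row, col) indices. Each pixel
    contributes its four corners (centre +/- 0.5), so a single pixel has
    hull area 1.0 and any region's hull area is at least its pixel count.
    Degenerate inputs fall back to the pixel count.
    """
    coords = np.asarray(pixel_coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError(f"expected (N, 2) coordinates, got {coords.shape}")
    n = len(coords)
    if n == 0:
        return 0.0
    offsets = np.array([[-0.5, -0.5], [-0.5, 0.5], [0.5, -0.5], [0.5, 0.5]])
    corners = (coords[:, None, :] + offsets[None, :, :]).reshape(-1, 2)
    try:
        return float(ConvexHull(corners).volume)
    except QhullError:
        return float(n)


def measure_rois(field: ImageField, label_map: LabelMap) -> list[RoiMeasurement]:
    """Measure every labelled ROI in a field.

    Returns one record per positive label, in label order. An empty label
    map yields an empty list.
    """
    labels = label_map.labels
    if labels.shape != field.pixels.shape:
        raise ValueError(
            f"label map shape {labels.shape} != field shape {field.pixels.shape}")
    if label_map.n_labels == 0:
        return []

    h, w = labels.shape
    out: list[RoiMeasurement] = []
    for region in measure.regionprops(labels, intensity_image=field.pixels):
        coords = region.coords
        values = field.pixels[coords[:, 0], coords[:, 1]]
        area = int(region.num_pixels)
        major = float(region.axis_major_length)
        minor = float(region.axis_minor_length)
        if major <= 0:
            aspect = 1.0
            roundness = 1.0
        else:
            aspect = math.inf if minor <= 0 else max(1.0, major / minor)
            roundness = 4.0 * area / (math.pi * major * major)
        minr, minc, maxr, maxc = region.bbox
        touches = minr == 0 or minc == 0 or maxr == h or maxc == w
        hull = convex_hull_area(coords)
        out.append(RoiMeasurement(
            roi_id=int(region.label),
            slide_id=field.slide_id,
            condition=field.condition,
            field_index=field.field_index,
            area_px=area,
            raw_integrated_density=float(values.sum(dtype=np.float64)),
            aspect_ratio=aspect,
            roundness=roundness,
            solidity=area / hull if hull > 0 else 1.0,
            min_brightness=float(values.min()),
            max_brightness=float(values.max()),
            touches_border=bool(touches),
            centroid=(float(region.centroid[0]), float(region.centroid[1])),
        ))
    return out
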