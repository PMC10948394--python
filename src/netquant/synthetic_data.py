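"""Seeded generator of NET-assay-like fields with per-object ground truth.

Each scene emulates one DAPI-stained field of vision: bright compact
nuclei, large diffuse NET clouds, dim small chromatin fragments, and
merged nuclear doublets over a noisy flat background. All intensities are
expressed as fractions of the bit-depth full scale and only converted to
integers at the very end.

The generator encodes the biological premise that makes the area/DNA
cutoffs meaningful:

* a *nucleus* is a uniform bright disk; its integrated intensity defines
  one "nucleus-equivalent" of DNA (up to area variation);
* a *NET* is an elongated, dim chromatin cloud at least five nucleus
  areas large whose total integrated intensity stays close to one
  nucleus-equivalent — the same DNA spread thin. Its brightness tapers
  from the centre outwards and a few-pixel bright remnant kernel marks
  the residual condensed chromatin at its core, as real NETs retain;
* a *doublet* is two touching nuclei (about two nucleus-equivalents);
* a *fragment* is a small shard of condensed chromatin at nuclear
  brightness but a twentieth of the area (far below half a
  nucleus-equivalent of DNA).

Objects never overlap except within doublets; splitting touching objects
is deliberately left to the downstream eliminations, not the segmenter.
Rendering is deterministic for a given spec + seed, noise is added last,
and ground-truth labels are drawn before noise.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import OvercrowdedSceneError, ValidationError
from .image_io import ImageField
from .net_calling import (
    ELIMINATED_BORDER,
    ELIMINATED_FRAGMENT,
    ELIMINATED_MULTIPLE,
    NET,
    NUCLEUS,
    RoiCall,
)
from .segmentation import LabelMap

CLASS_NUCLEUS = "nucleus"
CLASS_NET = "net"
CLASS_FRAGMENT = "fragment"
CLASS_DOUBLET = "doublet"
CLASSES = (CLASS_NUCLEUS, CLASS_NET, CLASS_FRAGMENT, CLASS_DOUBLET)

#: which truth class each pipeline call ideally lands on
CALL_TO_CATEGORY = {
    NUCLEUS: "nucleus",
    NET: "net",
    ELIMINATED_FRAGMENT: "fragment",
    ELIMINATED_MULTIPLE: "multiple",
    ELIMINATED_BORDER: "border",
}


@dataclass
class SceneSpec:
    """Parameters of one synthetic field.

    Intensity-like values (background, noise, peaks) are fractions of the
    full scale of ``bit_depth``. Areas are in pixels. The defaults portray
    a field of ~20 neutrophils at 600x magnification where nuclei occupy
    about 240 px and NETs read roughly an order of magnitude dimmer than
    nuclei but clearly above background. The nucleus peak sits just below
    saturation, mirroring the usual practice of exposing DAPI acquisitions
    on the condensed nuclei.
    """

    shape: tuple[int, int] = (512, 512)
    bit_depth: int = 16
    background: float = 0.02
    noise_sd: float = 0.005
    n_nuclei: int = 20
    n_nets: int = 5
    n_fragments: int = 3
    n_doublets: int = 2
    nucleus_area_mean: float = 240.0
    nucleus_area_sd: float = 20.0
    nucleus_peak: float = 0.95
    net_area_mult: tuple[float, float] = (5.0, 6.0)
    net_dna_equiv: tuple[float, float] = (1.0, 1.2)
    net_aspect: tuple[float, float] = (3.0, 5.0)
    net_kernel_area: float = 9.0
    fragment_area: tuple[float, float] = (10.0, 16.0)
    doublet_area_sd_frac: float = 0.04
    doublet_offset: float = 1.9   # centre distance in units of the mean radius
    min_spacing: float = 6.0
    max_place_attempts: int = 5000
    rng_seed: int = 0

    def __post_init__(self):
        for name in ("n_nuclei", "n_nets", "n_fragments", "n_doublets"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not (0 < self.nucleus_peak <= 1):
            raise ValidationError("nucleus_peak must be in (0, 1]")
        if self.net_area_mult[0] < 1:
            raise ValidationError("NET area multiplier must be >= 1")

    @property
    def nucleus_equivalent(self) -> float:
        """Integrated intensity of one nominal nucleus, in fractional units."""
        return self.nucleus_area_mean * self.nucleus_peak


@dataclass
class GroundTruth:
    """Per-object truth for one generated field."""

    labels: np.ndarray
    classes: list[str]                      # class of label i at index i-1
    areas: list[int]
    integrated_intensities: list[float]     # object signal sum, image units
    nucleus_equivalent: float               # one nucleus of DNA, image units

    @property
    def n_objects(self) -> int:
        return len(self.classes)

    @property
    def true_net_fraction(self) -> float:
        n_net = self.classes.count(CLASS_NET)
        n_nuc = self.classes.count(CLASS_NUCLEUS)
        return n_net / (n_net + n_nuc) if (n_net + n_nuc) else math.nan

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "object_id": np.arange(1, self.n_objects + 1),
            "class": self.classes,
            "area_px": self.areas,
            "integrated_intensity": self.integrated_intensities,
        })


def derive_field_seed(master_seed: int, slide_id: str, field_index: int) -> int:
    """Stable per-field seed from (master seed, slide, field), below 2**31."""
    token = f"{master_seed}:{slide_id}:{field_index}".encode()
    return zlib.crc32(token) & 0x7FFFFFFF


def _disk_mask(shape, center, radius):
    r0 = max(0, int(math.floor(center[0] - radius - 1)))
    r1 = min(shape[0], int(math.ceil(center[0] + radius + 2)))
    c0 = max(0, int(math.floor(center[1] - radius - 1)))
    c1 = min(shape[1], int(math.ceil(center[1] + radius + 2)))
    rows, cols = np.mgrid[r0:r1, c0:c1]
    inside = (rows - center[0]) ** 2 + (cols - center[1]) ** 2 <= radius ** 2
    return (slice(r0, r1), slice(c0, c1)), inside


def _ellipse_rho(shape, center, semi_major, semi_minor, theta):
    """Elliptical radius (1.0 on the boundary) over the bounding box."""
    pad = semi_major + 2
    r0 = max(0, int(center[0] - pad))
    r1 = min(shape[0], int(center[0] + pad) + 1)
    c0 = max(0, int(center[1] - pad))
    c1 = min(shape[1], int(center[1] + pad) + 1)
    rows, cols = np.mgrid[r0:r1, c0:c1]
    dy = rows - center[0]
    dx = cols - center[1]
    u = dy * math.cos(theta) + dx * math.sin(theta)
    v = -dy * math.sin(theta) + dx * math.cos(theta)
    rho = np.sqrt((u / semi_major) ** 2 + (v / semi_minor) ** 2)
    return (slice(r0, r1), slice(c0, c1)), rho


class _Placer:
    """Rejection sampler keeping object bounding circles apart."""

    def __init__(self, spec: SceneSpec, rng: np.random.Generator):
        self.spec = spec
        self.rng = rng
        self.placed: list[tuple[float, float, float]] = []

    def place(self, bounding_radius: float, object_class: str) -> tuple[float, float]:
        h, w = self.spec.shape
        margin = bounding_radius + 3.0
        if 2 * margin >= min(h, w):
            raise OvercrowdedSceneError(
                f"a {object_class} of radius {bounding_radius:.0f} px does not "
                f"fit a {h}x{w} field", object_class=object_class)
        for _ in range(self.spec.max_place_attempts):
            cy = self.rng.uniform(margin, h - margin)
            cx = self.rng.uniform(margin, w - margin)
            ok = all(
                math.hypot(cy - py, cx - px) > bounding_radius + pr
                + self.spec.min_spacing
                for py, px, pr in self.placed)
            if ok:
                self.placed.append((cy, cx, bounding_radius))
                return cy, cx
        raise OvercrowdedSceneError(
            f"could not place a {object_class} after "
            f"{self.spec.max_place_attempts} attempts", object_class=object_class)


def generate_field(
    spec: SceneSpec,
    *,
    slide_id: str = "sim",
    condition: str = "spontaneous",
    field_index: int = 1,
) -> tuple[ImageField, GroundTruth]:
    """Render one synthetic field and its ground truth.

    Deterministic for a given (spec, rng_seed). Raises
    :class:`OvercrowdedSceneError` when the requested objects cannot be
    placed without overlap, naming the failing class.
    """
    rng = np.random.default_rng(spec.rng_seed)
    canvas = np.zeros(spec.shape, dtype=np.float64)
    labels = np.zeros(spec.shape, dtype=np.int32)
    classes: list[str] = []
    placer = _Placer(spec, rng)

    def paint(sl, mask, values, object_class):
        region = canvas[sl]
        canvas[sl] = np.where(mask, np.maximum(region, values), region)
        lab = labels[sl]
        lab[mask] = len(classes) + 1
        labels[sl] = lab
        classes.append(object_class)

    def sample_nucleus_area(sd):
        # truncated at 1.5 sd so doublet DNA stays near two nucleus-equivalents
        return float(np.clip(rng.normal(spec.nucleus_area_mean, sd),
                             spec.nucleus_area_mean - 1.5 * sd,
                             spec.nucleus_area_mean + 1.5 * sd))

    # NETs first: the largest objects are hardest to place.
    for _ in range(spec.n_nets):
        mult = rng.uniform(*spec.net_area_mult)
        aspect = rng.uniform(*spec.net_aspect)
        dna = rng.uniform(*spec.net_dna_equiv) * spec.nucleus_equivalent
        area = mult * spec.nucleus_area_mean
        semi_minor = math.sqrt(area / (math.pi * aspect))
        semi_major = semi_minor * aspect
        theta = rng.uniform(0, math.pi)
        cy, cx = placer.place(semi_major + 2, CLASS_NET)
        sl, rho = _ellipse_rho(spec.shape, (cy, cx), semi_major, semi_minor, theta)
        mask = rho <= 1.0
        # centre-weighted taper, unit mean over the footprint: 1.5 - 0.75*rho
        taper = np.where(mask, 1.5 - 0.75 * rho, 0.0)
        kernel_radius = math.sqrt(spec.net_kernel_area / math.pi)
        # bright remnant kernel expressed on the ellipse's bounding box
        ks, kin = _disk_mask(spec.shape, (cy, cx), kernel_radius)
        sub = np.zeros(spec.shape, dtype=bool)
        sub[ks] = kin
        kmask = sub[sl] & mask
        taper_sum = taper[~kmask].sum()
        kernel_dna = kmask.sum() * spec.nucleus_peak
        amp = max((dna - kernel_dna), 0.0) / taper_sum if taper_sum > 0 else 0.0
        values = amp * taper
        values[kmask] = spec.nucleus_peak
        paint(sl, mask, values, CLASS_NET)

    for _ in range(spec.n_doublets):
        a1 = sample_nucleus_area(spec.doublet_area_sd_frac * spec.nucleus_area_mean)
        a2 = sample_nucleus_area(spec.doublet_area_sd_frac * spec.nucleus_area_mean)
        r1 = math.sqrt(a1 / math.pi)
        r2 = math.sqrt(a2 / math.pi)
        d = spec.doublet_offset * (r1 + r2) / 2.0
        bound = d / 2.0 + max(r1, r2)
        cy, cx = placer.place(bound, CLASS_DOUBLET)
        theta = rng.uniform(0, math.pi)
        off = (d / 2.0 * math.cos(theta), d / 2.0 * math.sin(theta))
        sub = np.zeros(spec.shape, dtype=bool)
        for (dy, dx), r in (((off[0], off[1]), r1), ((-off[0], -off[1]), r2)):
            s, inside = _disk_mask(spec.shape, (cy + dy, cx + dx), r)
            sub[s] |= inside
        sl = (slice(None), slice(None))
        paint(sl, sub, np.where(sub, spec.nucleus_peak, 0.0), CLASS_DOUBLET)

    for _ in range(spec.n_nuclei):
        area = sample_nucleus_area(spec.nucleus_area_sd)
        radius = math.sqrt(area / math.pi)
        cy, cx = placer.place(radius, CLASS_NUCLEUS)
        sl, inside = _disk_mask(spec.shape, (cy, cx), radius)
        paint(sl, inside, np.where(inside, spec.nucleus_peak, 0.0), CLASS_NUCLEUS)

    for _ in range(spec.n_fragments):
        area = rng.uniform(*spec.fragment_area)
        radius = math.sqrt(area / math.pi)
        cy, cx = placer.place(radius, CLASS_FRAGMENT)
        sl, inside = _disk_mask(spec.shape, (cy, cx), radius)
        paint(sl, inside, np.where(inside, spec.nucleus_peak, 0.0), CLASS_FRAGMENT)

    max_value = 2 ** spec.bit_depth - 1
    areas = [int((labels == i).sum()) for i in range(1, len(classes) + 1)]
    intensities = [float(canvas[labels == i].sum() * max_value)
                   for i in range(1, len(classes) + 1)]

    noisy = spec.background + canvas + rng.normal(0.0, spec.noise_sd, spec.shape)
    clipped = np.count_nonzero((noisy < 0) | (noisy > 1))
    if clipped > 0.001 * noisy.size:
        raise ValidationError(
            f"{clipped} of {noisy.size} pixels clip the bit depth; "
            "lower the object intensities or the noise")
    image = np.round(np.clip(noisy, 0.0, 1.0) * max_value)
    dtype = np.uint8 if spec.bit_depth == 8 else np.uint16
    field = ImageField(pixels=image.astype(dtype), bit_depth=spec.bit_depth,
                       slide_id=slide_id, condition=condition,
                       field_index=field_index)
    truth = GroundTruth(labels=labels, classes=classes, areas=areas,
                        integrated_intensities=intensities,
                        nucleus_equivalent=spec.nucleus_equivalent * max_value)
    return field, truth


@dataclass
class TruthEvaluation:
    """Detection-vs-truth confusion and the NET percentage error."""

    confusion: pd.DataFrame          # rows: truth classes; cols: call categories
    n_unmatched_detections: int
    matched_pairs: list[tuple[int, int, float]]  # (det label, truth label, IoU)
    net_percent_auto: float
    net_percent_true: float

    @property
    def net_percent_abs_error(self) -> float:
        return abs(self.net_percent_auto - self.net_percent_true)

    def call_rate(self, truth_class: str, category: str) -> float:
        """Fraction of matched objects of a truth class given a category call."""
        row = self.confusion.loc[truth_class]
        matched = row.drop("unmatched").sum()
        return row[category] / matched if matched else math.nan


def evaluate_against_truth(
    label_map: LabelMap,
    calls: Sequence[RoiCall],
    truth: GroundTruth,
    iou_min: float = 0.5,
) -> TruthEvaluation:
    """Match detected ROIs to ground-truth objects and tabulate calls.

    Detections are matched one-to-one to truth objects greedily by
    decreasing pixel-overlap IoU, keeping only matches with IoU >=
    ``iou_min``. The confusion table rows are truth classes (plus their
    "unmatched" = missed column); unmatched detections are counted
    separately.
    """
    det = label_map.labels
    if det.shape != truth.labels.shape:
        raise ValidationError(
            f"detection shape {det.shape} != truth shape {truth.labels.shape}")

    call_by_id = {c.roi_id: c.call for c in calls}
    det_ids = np.arange(1, label_map.n_labels + 1)
    truth_ids = np.arange(1, truth.n_objects + 1)

    both = (det > 0) & (truth.labels > 0)
    pair_counts: dict[tuple[int, int], int] = {}
    if both.any():
        pairs = np.stack([det[both], truth.labels[both]], axis=1)
        uniq, counts = np.unique(pairs, axis=0, return_counts=True)
        pair_counts = {(int(d), int(t)): int(c) for (d, t), c in zip(uniq, counts)}

    det_areas = np.bincount(det.ravel(), minlength=label_map.n_labels + 1)
    truth_areas = np.bincount(truth.labels.ravel(), minlength=truth.n_objects + 1)

    candidates = []
    for (d, t), inter in pair_counts.items():
        union = det_areas[d] + truth_areas[t] - inter
        iou = inter / union if union else 0.0
        if iou >= iou_min:
            candidates.append((iou, d, t))
    candidates.sort(key=lambda x: (-x[0], x[1], x[2]))

    matched_det: set[int] = set()
    matched_truth: set[int] = set()
    matches: list[tuple[int, int, float]] = []
    for iou, d, t in candidates:
        if d in matched_det or t in matched_truth:
            continue
        matched_det.add(d)
        matched_truth.add(t)
        matches.append((d, t, iou))

    categories = ["nucleus", "net", "fragment", "multiple", "border", "unmatched"]
    confusion = pd.DataFrame(0, index=list(CLASSES), columns=categories)
    for d, t, _ in matches:
        cls = truth.classes[t - 1]
        category = CALL_TO_CATEGORY.get(call_by_id.get(d, ""), "unmatched")
        confusion.loc[cls, category] += 1
    for t in truth_ids:
        if t not in matched_truth:
            confusion.loc[truth.classes[t - 1], "unmatched"] += 1
    n_unmatched_det = int(len(det_ids) - len(matched_det))

    n_nets = sum(1 for c in calls if c.call == NET)
    n_nuclei = sum(1 for c in calls if c.call == NUCLEUS)
    auto = 100.0 * n_nets / (n_nets + n_nuclei) if (n_nets + n_nuclei) else math.nan
    true = 100.0 * truth.true_net_fraction
    return TruthEvaluation(
        confusion=confusion,
        n_unmatched_detections=n_unmatched_det,
        matched_pairs=matches,
        net_percent_auto=auto,
        net_percent_true=true,
    )


def scene_for_fraction(
    net_fraction: float,
    n_cells: int = 20,
    seed: int = 0,
    **overrides,
) -> SceneSpec:
    """A scene whose true NET fraction among cells equals ``net_fraction``.

    ``n_cells`` counts nuclei + NETs; doublets and fragments ride along at
    their default counts.
    """
    n_nets = round(net_fraction * n_cells)
    spec = SceneSpec(n_nuclei=n_cells - n_nets, n_nets=n_nets,
                     rng_seed=seed, **overrides)
    return spec
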