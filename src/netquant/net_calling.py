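"""Classify measured ROIs as nuclei, NETs, or eliminated objects.

The biological premise: a NET carries roughly one nucleus worth of DNA
spread over a much larger, dimmer area, whereas a condensed nucleus is
compact and bright. Two relative quantities therefore drive every call:

* ``relative_area`` — ROI area divided by the condensed-nucleus reference
  area of the field. At or above the NET cutoff (default 4.30) the ROI is
  a NET.
* ``relative_dna`` — raw integrated density divided by the median raw
  integrated density of the field's border-filtered ROIs. Strictly below
  the lower cutoff (default 0.5) the ROI is a cell fragment; strictly
  above the upper elimination cutoff (default 1.2) a non-NET ROI is a
  multiple (doublet or clump). The upper cutoff is applied to DNA content,
  the only reading under which 1.2 < 4.30 coherently separates doublets
  (about twice the DNA) from NETs (same DNA, larger area).

The decision sequence is fixed: border exclusion, fragment elimination,
NET call, multiple elimination, nucleus. NETs are called *before* the
upper elimination because a diffuse halo can push a NET's relative DNA
slightly above 1.2; eliminating first would systematically under-call
NETs. Cutoff inclusivity is fixed (NET at >= cutoff, eliminations strict)
so results are bit-reproducible.

The condensed-nucleus reference area is a median with iterative NET
exclusion, seeded from the lower area quartile: candidates whose area
ratio against the running reference reaches the NET cutoff are excluded
and the median of the remainder is recomputed until stable. The low-
quartile seed keeps the estimator anchored on nuclei even when NETs make
up half of all objects, where a plain median would be inflated past the
point of ever excluding them.

The per-slide NET percentage pools counts across fields — NET-like
structures divided by the total number of retained neutrophils — rather
than averaging per-field percentages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field, replace
from typing import Optional, Sequence

import numpy as np
import yaml

from .errors import (
    DegenerateReferenceError,
    NoReferenceError,
    ValidationError,
)
from .roi_features import RoiMeasurement

NUCLEUS = "nucleus"
NET = "net"
ELIMINATED_FRAGMENT = "eliminated_fragment"
ELIMINATED_MULTIPLE = "eliminated_multiple"
ELIMINATED_BORDER = "eliminated_border"
CALLS = (NUCLEUS, NET, ELIMINATED_FRAGMENT, ELIMINATED_MULTIPLE, ELIMINATED_BORDER)


@dataclass
class SegmentationSettings:
    """Knobs of the two-threshold segmenter; defaults are the published ones."""

    n_bins: int = 256
    max_smooth_iters: int = 10_000
    on_unimodal: str = "error"  # or "otsu_fallback"
    phansalkar_radius: int = 15
    phansalkar_k: float = 0.25
    phansalkar_r: float = 0.5
    phansalkar_p: float = 2.0
    phansalkar_q: float = 10.0
    combine_mode: str = "local_seeded_by_global"
    connectivity: int = 8
    min_area_px: int = 10


@dataclass
class PipelineConfig:
    """Cutoffs and policies for ROI classification.

    ``net_area_cutoff`` and ``upper_elim_cutoff`` are the optimised values
    used on the clinical images; ``lower_elim_cutoff`` (fragments carry
    less than half a nucleus of DNA) is a documented, configurable default.
    """

    net_area_cutoff: float = 4.30
    upper_elim_cutoff: float = 1.2
    lower_elim_cutoff: float = 0.5
    exclude_border: bool = True
    min_rois_for_field_reference: int = 10
    segmentation: SegmentationSettings = dc_field(default_factory=SegmentationSettings)
    channel_policy: str | int = "gray"

    def __post_init__(self):
        if not (self.net_area_cutoff > self.upper_elim_cutoff
                > self.lower_elim_cutoff > 0):
            raise ValidationError(
                "cutoffs must satisfy net_area_cutoff > upper_elim_cutoff "
                f"> lower_elim_cutoff > 0, got {self.net_area_cutoff} / "
                f"{self.upper_elim_cutoff} / {self.lower_elim_cutoff}")

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data or {})
        seg = data.pop("segmentation", {}) or {}
        known_seg = {k: v for k, v in seg.items()
                     if k in SegmentationSettings.__dataclass_fields__}
        known = {k: v for k, v in data.items()
                 if k in cls.__dataclass_fields__ and k != "segmentation"}
        return cls(segmentation=SegmentationSettings(**known_seg), **known)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        out = {k: getattr(self, k) for k in self.__dataclass_fields__
               if k != "segmentation"}
        out["segmentation"] = dict(self.segmentation.__dict__)
        return out


@dataclass
class RoiCall:
    """Classification of one ROI with the relative metrics that drove it."""

    roi_id: int
    relative_area: float
    relative_dna: float
    call: str


@dataclass
class ReferenceStats:
    """Per-field (or pooled) denominators for the relative metrics."""

    dna_reference: float       # median raw integrated density, border-filtered
    area_reference: float      # condensed-nucleus reference area
    n_reference_rois: int      # ROIs the statistics were computed from
    pooled: bool = False       # True when borrowed from the slide-condition pool


@dataclass
class FieldResult:
    slide_id: str
    condition: str
    field_index: int
    n_total_retained: int
    n_nets: int
    n_nuclei: int
    n_fragment: int
    n_multiple: int
    n_border: int
    reference_area: float
    average_cellular_dna: float
    status: str = "ok"


@dataclass
class SlideResult:
    """Pooled per-slide-per-condition NET percentage and supporting counts."""

    slide_id: str
    condition: str
    group: str
    n_fields: int
    total_retained: int
    total_nets: int
    net_percent: float
    manual_override: Optional[float] = None
    flags: tuple[str, ...] = ()

    @property
    def final_net_percent(self) -> float:
        return self.net_percent if self.manual_override is None else self.manual_override

    def with_override(self, value: float) -> "SlideResult":
        return replace(self, manual_override=value,
                       flags=tuple(dict.fromkeys((*self.flags, "manual"))))


def reference_area(
    measurements: Sequence[RoiMeasurement],
    net_area_cutoff: float = 4.30,
) -> tuple[float, set[int]]:
    """Condensed-nucleus reference area with iterative NET-candidate exclusion.

    Candidates are seeded from the ratio against the lower area quartile,
    then the reference is the median area of non-candidates; any ROI whose
    area ratio against the reference reaches ``net_area_cutoff`` joins the
    candidate set, and the loop repeats until stable. The candidate set
    only ever grows, so at most n iterations run.

    Returns (reference_area, set of candidate roi_ids).
    """
    if not measurements:
        raise NoReferenceError("no ROIs available to form a reference area")
    areas = np.array([m.area_px for m in measurements], dtype=float)
    ids = [m.roi_id for m in measurements]

    seed_ref = float(np.percentile(areas, 25))
    candidates = set(np.flatnonzero(areas / seed_ref >= net_area_cutoff))
    while True:
        keep = [i for i in range(len(areas)) if i not in candidates]
        if not keep:
            raise DegenerateReferenceError(
                "every ROI is a NET candidate; no condensed-nucleus reference")
        ref = float(np.median(areas[keep]))
        new = candidates | set(np.flatnonzero(areas / ref >= net_area_cutoff))
        if new == candidates:
            return ref, {ids[i] for i in candidates}
        candidates = new


def reference_stats(
    measurements: Sequence[RoiMeasurement],
    config: PipelineConfig,
    pooled: bool = False,
) -> ReferenceStats:
    """Compute the relative-metric denominators from a measurement pool.

    The DNA reference is the median raw integrated density of
    border-filtered ROIs (a robust single-pass choice; the reported
    "average cellular DNA" is deliberately not reused here to avoid
    circularity). The area reference additionally excludes fragments.
    """
    pool = [m for m in measurements
            if not (config.exclude_border and m.touches_border)]
    if not pool:
        raise NoReferenceError("no non-border ROIs to form reference statistics")
    rids = np.array([m.raw_integrated_density for m in pool], dtype=float)
    dna_ref = float(np.median(rids))
    if dna_ref <= 0:
        raise DegenerateReferenceError("median raw integrated density is zero")
    non_fragment = [m for m in pool
                    if m.raw_integrated_density / dna_ref >= config.lower_elim_cutoff]
    if not non_fragment:
        raise DegenerateReferenceError("all ROIs classify as fragments")
    area_ref, _ = reference_area(non_fragment, config.net_area_cutoff)
    return ReferenceStats(dna_reference=dna_ref, area_reference=area_ref,
                          n_reference_rois=len(pool), pooled=pooled)


def classify_rois(
    measurements: Sequence[RoiMeasurement],
    config: PipelineConfig,
    stats: Optional[ReferenceStats] = None,
) -> list[RoiCall]:
    """Apply the fixed decision sequence to every measured ROI.

    ``stats`` defaults to statistics computed from ``measurements``
    themselves; for sparse fields the caller passes pooled statistics from
    the whole slide-condition instead.
    """
    if not measurements:
        return []
    if stats is None:
        stats = reference_stats(measurements, config)

    calls: list[RoiCall] = []
    for m in measurements:
        rel_dna = m.raw_integrated_density / stats.dna_reference
        rel_area = m.area_px / stats.area_reference
        if config.exclude_border and m.touches_border:
            call = ELIMINATED_BORDER
        elif rel_dna < config.lower_elim_cutoff:
            call = ELIMINATED_FRAGMENT
        elif rel_area >= config.net_area_cutoff:
            call = NET
        elif rel_dna > config.upper_elim_cutoff:
            call = ELIMINATED_MULTIPLE
        else:
            call = NUCLEUS
        calls.append(RoiCall(roi_id=m.roi_id, relative_area=rel_area,
                             relative_dna=rel_dna, call=call))
    return calls


def field_summary(
    calls: Sequence[RoiCall],
    measurements: Sequence[RoiMeasurement],
    stats: Optional[ReferenceStats] = None,
    *,
    slide_id: str = "",
    condition: str = "",
    field_index: int = 1,
    status: str = "ok",
) -> FieldResult:
    """Aggregate per-ROI calls into the per-image counts.

    Average cellular DNA is the mean raw integrated density over retained
    ROIs (nuclei plus NETs); with zero retained ROIs it is reported as NaN.
    """
    if measurements:
        slide_id = slide_id or measurements[0].slide_id
        condition = condition or measurements[0].condition
        field_index = measurements[0].field_index if measurements else field_index
    by_id = {m.roi_id: m for m in measurements}
    counts = {c: 0 for c in CALLS}
    retained_dna: list[float] = []
    for call in calls:
        counts[call.call] += 1
        if call.call in (NUCLEUS, NET):
            retained_dna.append(by_id[call.roi_id].raw_integrated_density)
    n_retained = counts[NUCLEUS] + counts[NET]
    return FieldResult(
        slide_id=slide_id,
        condition=condition,
        field_index=field_index,
        n_total_retained=n_retained,
        n_nets=counts[NET],
        n_nuclei=counts[NUCLEUS],
        n_fragment=counts[ELIMINATED_FRAGMENT],
        n_multiple=counts[ELIMINATED_MULTIPLE],
        n_border=counts[ELIMINATED_BORDER],
        reference_area=stats.area_reference if stats else math.nan,
        average_cellular_dna=float(np.mean(retained_dna)) if retained_dna else math.nan,
        status=status,
    )


def slide_summary(
    field_results: Sequence[FieldResult],
    group: str = "",
) -> SlideResult:
    """Pool field counts into the slide-level NET percentage.

    net_percent = 100 * (sum of NETs) / (sum of retained ROIs), pooled
    across fields. A slide with zero retained ROIs gets NaN and a QC flag.
    """
    if not field_results:
        raise ValidationError("slide_summary requires at least one field result")
    idents = {(f.slide_id, f.condition) for f in field_results}
    if len(idents) != 1:
        raise ValidationError(
            f"fields from multiple slide/conditions pooled together: {sorted(idents)}")
    slide_id, condition = next(iter(idents))
    total_nets = sum(f.n_nets for f in field_results)
    total_retained = sum(f.n_total_retained for f in field_results)
    flags: tuple[str, ...] = ()
    if total_retained > 0:
        net_percent = 100.0 * total_nets / total_retained
    else:
        net_percent = math.nan
        flags = ("no_retained_rois",)
    return SlideResult(
        slide_id=slide_id, condition=condition, group=group,
        n_fields=len(field_results), total_retained=total_retained,
        total_nets=total_nets, net_percent=net_percent, flags=flags)
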