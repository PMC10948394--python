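"""End-to-end orchestration: segmentation -> features -> calls -> pooling.

Fields are processed independently, then classified within their
(slide, condition) group so that sparse fields — fewer non-border ROIs
than ``min_rois_for_field_reference`` — can borrow reference statistics
from the pooled group instead of their own unreliable handful of objects.
A field that fails (unreadable file, non-bimodal histogram without a
configured fallback, degenerate reference) is recorded with a status and
zero counts rather than aborting the run.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DegenerateReferenceError,
    NetQuantError,
    NoReferenceError,
    NotBimodalError,
)
from .image_io import (
    FIELD_COLUMNS,
    ROI_COLUMNS,
    SLIDE_COLUMNS,
    ImageField,
    SlideManifest,
    load_field,
)
from .net_calling import (
    FieldResult,
    PipelineConfig,
    ReferenceStats,
    RoiCall,
    SlideResult,
    classify_rois,
    field_summary,
    reference_stats,
    slide_summary,
)
from .roi_features import RoiMeasurement, measure_rois
from .segmentation import (
    LabelMap,
    combine_masks,
    intermodes_threshold,
    label_components,
    phansalkar_threshold,
)

logger = logging.getLogger(__name__)


@dataclass
class FieldOutput:
    field_index: int
    slide_id: str
    condition: str
    label_map: Optional[LabelMap]
    measurements: list[RoiMeasurement]
    calls: list[RoiCall] = dc_field(default_factory=list)
    result: Optional[FieldResult] = None
    status: str = "ok"


@dataclass
class QuantifyOutput:
    rois: pd.DataFrame
    fields: pd.DataFrame
    slides: pd.DataFrame
    slide_results: list[SlideResult]
    field_outputs: list[FieldOutput]


def segment_field(field: ImageField, config: PipelineConfig) -> LabelMap:
    """Two-threshold segmentation of one field into labelled ROIs."""
    seg = config.segmentation
    try:
        threshold = intermodes_threshold(
            field.pixels, n_bins=seg.n_bins, max_smooth_iters=seg.max_smooth_iters)
    except NotBimodalError:
        if seg.on_unimodal != "otsu_fallback":
            raise
        from skimage.filters import threshold_otsu
        threshold = float(threshold_otsu(field.pixels))
    global_fg = field.pixels > threshold
    local_fg = phansalkar_threshold(
        field.pixels, radius=seg.phansalkar_radius, k=seg.phansalkar_k,
        r=seg.phansalkar_r, p=seg.phansalkar_p, q=seg.phansalkar_q,
        bit_depth=field.bit_depth)
    combined = combine_masks(global_fg, local_fg, mode=seg.combine_mode,
                             connectivity=seg.connectivity)
    return label_components(combined, connectivity=seg.connectivity,
                            min_area_px=seg.min_area_px)


def process_field(
    field: ImageField, config: PipelineConfig
) -> tuple[LabelMap, list[RoiMeasurement]]:
    """Segment and measure one field."""
    label_map = segment_field(field, config)
    return label_map, measure_rois(field, label_map)


def _n_reference_rois(measurements: Sequence[RoiMeasurement],
                      config: PipelineConfig) -> int:
    return sum(1 for m in measurements
               if not (config.exclude_border and m.touches_border))


def quantify_fields(
    fields: Sequence[ImageField],
    config: Optional[PipelineConfig] = None,
    groups: Optional[dict[tuple[str, str], str]] = None,
) -> QuantifyOutput:
    """Run the full pipeline over in-memory fields.

    ``groups`` maps (slide_id, condition) to the experimental group label
    used for QC stratification; missing entries default to "".
    """
    config = config or PipelineConfig()
    groups = groups or {}

    outputs: list[FieldOutput] = []
    for field in fields:
        out = FieldOutput(field_index=field.field_index, slide_id=field.slide_id,
                          condition=field.condition, label_map=None,
                          measurements=[])
        try:
            out.label_map, out.measurements = process_field(field, config)
        except NotBimodalError as exc:
            out.status = "failed:not_bimodal"
            logger.warning("field %s/%s/%d: %s", field.slide_id, field.condition,
                           field.field_index, exc)
        outputs.append(out)

    return _classify_and_pool(outputs, config, groups)


def _classify_and_pool(
    outputs: list[FieldOutput],
    config: PipelineConfig,
    groups: dict[tuple[str, str], str],
) -> QuantifyOutput:
    by_group: dict[tuple[str, str], list[FieldOutput]] = {}
    for out in outputs:
        by_group.setdefault((out.slide_id, out.condition), []).append(out)

    slide_results: list[SlideResult] = []
    for key in sorted(by_group):
        members = by_group[key]
        pooled_measurements = [m for o in members for m in o.measurements]
        pooled_stats: Optional[ReferenceStats] = None
        field_results = []
        for out in members:
            stats: Optional[ReferenceStats] = None
            status = out.status
            if status == "ok" and out.measurements:
                try:
                    if (_n_reference_rois(out.measurements, config)
                            < config.min_rois_for_field_reference):
                        if pooled_stats is None:
                            pooled_stats = reference_stats(
                                pooled_measurements, config, pooled=True)
                        stats = pooled_stats
                    else:
                        stats = reference_stats(out.measurements, config)
                    out.calls = classify_rois(out.measurements, config, stats)
                except (NoReferenceError, DegenerateReferenceError) as exc:
                    status = "flagged:no_reference"
                    out.calls = []
                    logger.warning("field %s/%s/%d flagged for manual review: %s",
                                   out.slide_id, out.condition,
                                   out.field_index, exc)
            out.result = field_summary(
                out.calls, out.measurements, stats,
                slide_id=out.slide_id, condition=out.condition,
                field_index=out.field_index, status=status)
            field_results.append(out.result)
        slide_results.append(
            slide_summary(field_results, group=groups.get(key, "")))

    return QuantifyOutput(
        rois=_rois_frame(outputs),
        fields=_fields_frame(outputs),
        slides=slides_frame(slide_results),
        slide_results=slide_results,
        field_outputs=outputs,
    )


def quantify_manifest(
    manifest: SlideManifest,
    config: Optional[PipelineConfig] = None,
) -> QuantifyOutput:
    """Load every manifest field and run the pipeline.

    An unreadable field is logged and recorded with a failed status; it
    contributes no ROIs but does not abort the run.
    """
    config = config or PipelineConfig()
    outputs: list[FieldOutput] = []
    for entry in manifest.entries:
        out = FieldOutput(field_index=entry.field_index, slide_id=entry.slide_id,
                          condition=entry.condition, label_map=None,
                          measurements=[])
        try:
            field = load_field(entry.path, channel_policy=config.channel_policy,
                               slide_id=entry.slide_id, condition=entry.condition,
                               field_index=entry.field_index)
            out.label_map, out.measurements = process_field(field, config)
        except NotBimodalError as exc:
            out.status = "failed:not_bimodal"
            logger.warning("field %s: %s", entry.path, exc)
        except (OSError, NetQuantError) as exc:
            out.status = "failed:unreadable"
            logger.warning("field %s could not be processed: %s", entry.path, exc)
        outputs.append(out)
    return _classify_and_pool(outputs, config, manifest.groups())


def _rois_frame(outputs: Sequence[FieldOutput]) -> pd.DataFrame:
    rows = []
    for out in outputs:
        call_by_id = {c.roi_id: c for c in out.calls}
        for m in out.measurements:
            call = call_by_id.get(m.roi_id)
            rows.append({
                "slide_id": m.slide_id, "condition": m.condition,
                "field_index": m.field_index, "roi_id": m.roi_id,
                "area_px": m.area_px,
                "raw_integrated_density": m.raw_integrated_density,
                "aspect_ratio": m.aspect_ratio, "roundness": m.roundness,
                "solidity": m.solidity, "min_brightness": m.min_brightness,
                "max_brightness": m.max_brightness,
                "touches_border": m.touches_border,
                "centroid_row": m.centroid[0], "centroid_col": m.centroid[1],
                "relative_area": call.relative_area if call else math.nan,
                "relative_dna": call.relative_dna if call else math.nan,
                "call": call.call if call else "",
            })
    return pd.DataFrame(rows, columns=ROI_COLUMNS)


def _fields_frame(outputs: Sequence[FieldOutput]) -> pd.DataFrame:
    rows = []
    for out in outputs:
        f = out.result
        rows.append({
            "slide_id": f.slide_id, "condition": f.condition,
            "field_index": f.field_index, "n_retained": f.n_total_retained,
            "n_nets": f.n_nets, "n_nuclei": f.n_nuclei,
            "n_fragment": f.n_fragment, "n_multiple": f.n_multiple,
            "n_border": f.n_border, "reference_area": f.reference_area,
            "average_cellular_dna": f.average_cellular_dna, "status": f.status,
        })
    return pd.DataFrame(rows, columns=FIELD_COLUMNS)


def slides_frame(slide_results: Sequence[SlideResult]) -> pd.DataFrame:
    rows = []
    for s in slide_results:
        rows.append({
            "slide_id": s.slide_id, "condition": s.condition, "group": s.group,
            "n_fields": s.n_fields, "total_retained": s.total_retained,
            "total_nets": s.total_nets, "net_percent": s.net_percent,
            "manual_override": (math.nan if s.manual_override is None
                                else s.manual_override),
            "final_net_percent": s.final_net_percent,
        })
    return pd.DataFrame(rows, columns=SLIDE_COLUMNS)
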