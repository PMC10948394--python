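"""Loading microscopy fields and slide manifests; writing result tables.

A *field* is one microscope field of vision: a single-channel grayscale
intensity matrix plus its identity within the experiment (slide, stimulation
condition, field number). Fields are organised by a CSV manifest, which is
the single source of slide/condition/group structure; nothing is inferred
from directory names.

Intensities are kept in their native integer range. Normalisation to [0, 1]
happens only inside thresholding operations that require it, so that raw
integrated density keeps its meaning as a DNA-content proxy.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Sequence, Union

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .errors import SchemaError, UnsupportedFormatError, ValidationError

logger = logging.getLogger(__name__)

#: minimum side length a field must have to be analysable
MIN_SIDE = 32

ROI_COLUMNS = [
    "slide_id", "condition", "field_index", "roi_id", "area_px",
    "raw_integrated_density", "aspect_ratio", "roundness", "solidity",
    "min_brightness", "max_brightness", "touches_border",
    "centroid_row", "centroid_col", "relative_area", "relative_dna", "call",
]
FIELD_COLUMNS = [
    "slide_id", "condition", "field_index", "n_retained", "n_nets",
    "n_nuclei", "n_fragment", "n_multiple", "n_border",
    "reference_area", "average_cellular_dna", "status",
]
SLIDE_COLUMNS = [
    "slide_id", "condition", "group", "n_fields", "total_retained",
    "total_nets", "net_percent", "manual_override", "final_net_percent",
]


@dataclass
class ImageField:
    """One microscopy field: intensity matrix plus its identity.

    ``pixels`` is a 2-D nonnegative integer array whose values fit the
    declared ``bit_depth`` (8 or 16).
    """

    pixels: np.ndarray
    bit_depth: int
    slide_id: str = ""
    condition: str = ""
    field_index: int = 1
    source_path: str = ""

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValidationError(
                f"field pixels must be 2-D, got shape {self.pixels.shape}")
        if min(self.pixels.shape) < MIN_SIDE:
            raise ValidationError(
                f"field smaller than {MIN_SIDE}x{MIN_SIDE}: {self.pixels.shape}")
        if self.bit_depth not in (8, 16):
            raise ValidationError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        lo = self.pixels.min()
        hi = self.pixels.max()
        if lo < 0 or hi > 2 ** self.bit_depth - 1:
            raise ValidationError(
                f"intensities [{lo}, {hi}] outside [0, {2 ** self.bit_depth - 1}]")
        if self.field_index < 1:
            raise ValidationError("field_index must be >= 1")

    @property
    def max_value(self) -> int:
        return 2 ** self.bit_depth - 1


@dataclass
class ManifestEntry:
    slide_id: str
    condition: str
    group: str
    field_index: int
    path: str


@dataclass
class SlideManifest:
    """Ordered list of fields grouped by slide and condition."""

    entries: list[ManifestEntry] = dc_field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def groups(self) -> dict[tuple[str, str], str]:
        """Map (slide_id, condition) -> group label."""
        return {(e.slide_id, e.condition): e.group for e in self.entries}


def _bit_depth_for(arr: np.ndarray, path: str) -> int:
    if arr.dtype == np.uint8:
        return 8
    if arr.dtype == np.uint16:
        return 16
    raise UnsupportedFormatError(
        f"{path}: dtype {arr.dtype} not supported (expected uint8 or uint16)")


def load_field(
    path: Union[str, os.PathLike],
    channel_policy: Union[str, int] = "gray",
    *,
    slide_id: str = "",
    condition: str = "",
    field_index: int = 1,
) -> ImageField:
    """Load a TIFF or PNG field without any intensity transformation.

    ``channel_policy`` is ``"gray"`` for single-channel input or a channel
    index for RGB input. DAPI lives in the blue channel by convention, so
    RGB images loaded with the default policy take channel 2; a luminance
    conversion is never applied because it would break integrated-density
    semantics.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image not found: {path}")
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            arr = tifffile.imread(str(path))
        else:
            arr = iio.imread(str(path))
    except Exception as exc:  # noqa: BLE001 - wrap reader-specific failures
        raise IOError(f"could not read image {path}: {exc}") from exc

    arr = np.asarray(arr)
    if arr.ndim == 3:
        if arr.shape[-1] > 3 or arr.shape[-1] < 2:
            raise UnsupportedFormatError(
                f"{path}: unsupported shape {arr.shape} "
                "(only 2-D grayscale or 3-channel planes are handled)")
        channel = 2 if channel_policy == "gray" else int(channel_policy)
        if channel >= arr.shape[-1]:
            raise UnsupportedFormatError(
                f"{path}: channel {channel} out of range for shape {arr.shape}")
        arr = arr[..., channel]
    elif arr.ndim != 2:
        raise UnsupportedFormatError(
            f"{path}: unsupported shape {arr.shape} "
            "(z-stacks and hyperstacks are out of scope)")
    elif isinstance(channel_policy, int):
        raise ValidationError(
            f"{path}: channel index {channel_policy} requested for a 2-D image")

    return ImageField(
        pixels=arr,
        bit_depth=_bit_depth_for(arr, str(path)),
        slide_id=slide_id,
        condition=condition,
        field_index=field_index,
        source_path=str(path),
    )


def load_manifest(path: Union[str, os.PathLike]) -> SlideManifest:
    """Read a slide manifest CSV.

    Required columns: ``slide_id, condition, group, field_path``. An
    optional ``field_index`` column is honoured; otherwise fields are
    numbered 1..n in row order within each (slide, condition). Relative
    image paths are resolved against the manifest's directory. Unknown
    extra columns are ignored with a warning.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    required = {"slide_id", "condition", "group", "field_path"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(
            f"manifest {path} missing columns {sorted(missing)}; "
            f"expected {sorted(required)} (optionally field_index)")
    extra = set(df.columns) - required - {"field_index"}
    if extra:
        logger.warning("manifest %s: ignoring extra columns %s", path, sorted(extra))

    base = path.parent
    counters: dict[tuple[str, str], int] = {}
    seen: set[tuple[str, str, int]] = set()
    entries: list[ManifestEntry] = []
    for _, row in df.iterrows():
        key = (row["slide_id"], row["condition"])
        if "field_index" in df.columns and not pd.isna(row.get("field_index")):
            idx = int(row["field_index"])
        else:
            counters[key] = counters.get(key, 0) + 1
            idx = counters[key]
        triple = (row["slide_id"], row["condition"], idx)
        if triple in seen:
            raise ValidationError(f"duplicate manifest entry {triple}")
        seen.add(triple)
        fp = Path(row["field_path"])
        if not fp.is_absolute():
            fp = base / fp
        if not fp.exists():
            raise ValidationError(f"manifest references missing file: {fp}")
        entries.append(ManifestEntry(
            slide_id=row["slide_id"], condition=row["condition"],
            group=row["group"], field_index=idx, path=str(fp)))
    return SlideManifest(entries=entries)


def _ordered(df: pd.DataFrame, columns: Sequence[str]) -> pd.DataFrame:
    out = df.copy()
    for col in columns:
        if col not in out.columns:
            out[col] = np.nan
    return out[list(columns)]


def write_results(
    rois: pd.DataFrame,
    fields: pd.DataFrame,
    slides: pd.DataFrame,
    out_dir: Union[str, os.PathLike],
) -> dict[str, str]:
    """Write the three result tables with their fixed column order.

    Floats are written with six decimal places so a round trip through the
    CSVs reproduces values to 6 decimals; integers round-trip exactly.
    Returns a mapping table name -> written path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = {}
    for name, df, cols in (
        ("rois", rois, ROI_COLUMNS),
        ("fields", fields, FIELD_COLUMNS),
        ("slides", slides, SLIDE_COLUMNS),
    ):
        target = out_dir / f"{name}.csv"
        _ordered(df, cols).to_csv(target, index=False, float_format="%.6f")
        written[name] = str(target)
    return written
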