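import numpy as np
import pytest

from netquant import PipelineConfig
from netquant.roi_features import RoiMeasurement


@pytest.fixture
def config():
    return PipelineConfig()


def make_measurement(
    roi_id,
    area_px=100,
    rid=None,
    touches_border=False,
    slide_id="s1",
    condition="spontaneous",
    field_index=1,
):
    """A RoiMeasurement with plausible defaults for classifier tests."""
    rid = float(area_px * 100) if rid is None else float(rid)
    return RoiMeasurement(
        roi_id=roi_id, slide_id=slide_id, condition=condition,
        field_index=field_index, area_px=area_px,
        raw_integrated_density=rid, aspect_ratio=1.0, roundness=1.0,
        solidity=1.0, min_brightness=50.0, max_brightness=150.0,
        touches_border=touches_border,
        centroid=(10.0, 10.0),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
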