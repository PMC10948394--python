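import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netquant import PipelineConfig
from netquant.errors import (
    DegenerateReferenceError,
    NoReferenceError,
    ValidationError,
)
from netquant.net_calling import (
    CALLS,
    classify_rois,
    field_summary,
    reference_area,
    slide_summary,
)

from conftest import make_measurement


class TestReferenceArea:
    def test_uniform_areas_have_no_candidates(self):
        ms = [make_measurement(i, area_px=100) for i in range(10)]
        ref, candidates = reference_area(ms)
        assert ref == 100
        assert candidates == set()

    def test_single_net_excluded_from_reference(self):
        # brute-force fixed point: ref stays at the nucleus median and the
        # 600 px object is a candidate (600 / 100 = 6.0 >= 4.30)
        ms = [make_measurement(i, area_px=100) for i in range(10)]
        ms.append(make_measurement(10, area_px=600))
        ref, candidates = reference_area(ms)
        assert ref == 100
        assert candidates == {10}

    def test_sparse_pair_under_calls(self):
        # {100, 430}: no seed candidate, median 265, 430/265 < 4.3 -> stable.
        # Documents why sparse fields borrow pooled reference statistics.
        ms = [make_measurement(0, area_px=100), make_measurement(1, area_px=430)]
        ref, candidates = reference_area(ms)
        assert ref == pytest.approx(265.0)
        assert candidates == set()

    def test_half_nets_still_anchored_on_nuclei(self):
        # at 50% NET prevalence a plain median would sit between the
        # populations and never exclude anything; the low-quartile seed keeps
        # the reference on the nucleus cluster
        ms = [make_measurement(i, area_px=240) for i in range(15)]
        ms += [make_measurement(100 + i, area_px=1300) for i in range(15)]
        ref, candidates = reference_area(ms)
        assert ref == 240
        assert candidates == {100 + i for i in range(15)}

    def test_empty_list_raises(self):
        with pytest.raises(NoReferenceError):
            reference_area([])

    def test_smallest_roi_never_becomes_candidate(self, rng):
        # the iterative exclusion can never exclude its own anchor: the
        # minimum-area ROI always stays in the reference set, so the
        # reference is always positive and well defined
        for _ in range(10):
            areas = rng.integers(10, 5000, size=rng.integers(1, 25))
            ms = [make_measurement(i, area_px=int(a))
                  for i, a in enumerate(areas)]
            ref, candidates = reference_area(ms)
            smallest = min(ms, key=lambda m: m.area_px).roi_id
            assert ref > 0
            assert smallest not in candidates


class TestClassifyRois:
    def _field(self, extra=()):
        ms = [make_measurement(i, area_px=100, rid=1000.0) for i in range(10)]
        ms.extend(extra)
        return ms

    def test_relative_area_exactly_at_cutoff_is_net(self, config):
        ms = self._field([make_measurement(10, area_px=430, rid=1000.0)])
        calls = {c.roi_id: c for c in classify_rois(ms, config)}
        assert calls[10].relative_area == pytest.approx(4.30)
        assert calls[10].call == "net"

    def test_typical_nucleus(self, config):
        ms = self._field()
        calls = classify_rois(ms, config)
        assert all(c.call == "nucleus" for c in calls)
        assert all(c.relative_dna == pytest.approx(1.0) for c in calls)

    def test_upper_elimination_strictly_greater(self, config):
        at_cutoff = self._field([make_measurement(10, area_px=100, rid=1200.0)])
        above = self._field([make_measurement(10, area_px=100, rid=1210.0)])
        assert classify_rois(at_cutoff, config)[-1].call == "nucleus"
        assert classify_rois(above, config)[-1].call == "eliminated_multiple"

    def test_fragment_below_lower_cutoff(self, config):
        ms = self._field([make_measurement(10, area_px=100, rid=490.0)])
        assert classify_rois(ms, config)[-1].call == "eliminated_fragment"

    def test_border_exclusion_precedes_everything(self, config):
        ms = self._field([make_measurement(10, area_px=430, rid=1000.0,
                                           touches_border=True)])
        assert classify_rois(ms, config)[-1].call == "eliminated_border"

    def test_net_called_before_upper_elimination(self, config):
        # a diffuse NET whose halo pushes relative DNA to 1.3 must stay a NET
        ms = self._field([make_measurement(10, area_px=500, rid=1300.0)])
        assert classify_rois(ms, config)[-1].call == "net"

    @given(st.lists(st.tuples(st.integers(50, 2000), st.floats(100, 1e6)),
                    min_size=1, max_size=40))
    @settings(max_examples=50, deadline=None)
    def test_partition_every_roi_gets_exactly_one_call(self, rois):
        config = PipelineConfig()
        ms = [make_measurement(i, area_px=a, rid=r) for i, (a, r) in enumerate(rois)]
        try:
            calls = classify_rois(ms, config)
        except DegenerateReferenceError:
            return
        assert len(calls) == len(ms)
        assert {c.roi_id for c in calls} == {m.roi_id for m in ms}
        assert all(c.call in CALLS for c in calls)

    @given(st.lists(st.integers(50, 3000), min_size=3, max_size=30),
           st.floats(2.0, 4.0), st.floats(4.3, 8.0))
    @settings(max_examples=50, deadline=None)
    def test_raising_net_cutoff_never_increases_nets(self, areas, lo_cut, hi_cut):
        ms = [make_measurement(i, area_px=a, rid=a * 10.0)
              for i, a in enumerate(areas)]

        def n_nets(cutoff):
            config = PipelineConfig(net_area_cutoff=cutoff)
            try:
                return sum(c.call == "net" for c in classify_rois(ms, config))
            except DegenerateReferenceError:
                return len(ms)

        assert n_nets(min(lo_cut, hi_cut)) >= n_nets(max(lo_cut, hi_cut))

    def test_intensity_scale_invariance(self, config):
        ms = self._field([make_measurement(10, area_px=430, rid=980.0),
                          make_measurement(11, area_px=100, rid=2600.0),
                          make_measurement(12, area_px=100, rid=300.0)])
        base = [c.call for c in classify_rois(ms, config)]
        for scale in (0.25, 7.0, 1000.0):
            scaled = [make_measurement(m.roi_id, area_px=m.area_px,
                                       rid=m.raw_integrated_density * scale,
                                       touches_border=m.touches_border)
                      for m in ms]
            assert [c.call for c in classify_rois(scaled, config)] == base

    def test_area_scale_invariance(self, config):
        ms = self._field([make_measurement(10, area_px=430, rid=1000.0)])
        base = [c.call for c in classify_rois(ms, config)]
        scaled = [make_measurement(m.roi_id, area_px=m.area_px * 4,
                                   rid=m.raw_integrated_density)
                  for m in ms]
        assert [c.call for c in classify_rois(scaled, config)] == base

    def test_empty_input_gives_empty_calls(self, config):
        assert classify_rois([], config) == []


class TestSummaries:
    def test_field_counts(self, config):
        ms = [make_measurement(i, area_px=100, rid=1000.0) for i in range(8)]
        ms += [make_measurement(8 + i, area_px=500, rid=1000.0) for i in range(2)]
        ms += [make_measurement(10, area_px=100, rid=300.0)]
        calls = classify_rois(ms, config)
        fr = field_summary(calls, ms)
        assert fr.n_total_retained == 10
        assert fr.n_nets == 2
        assert fr.n_nuclei == 8
        assert fr.n_fragment == 1
        assert fr.n_total_retained == fr.n_nets + fr.n_nuclei

    def test_average_cellular_dna_is_mean_over_retained(self, config):
        ms = [make_measurement(0, area_px=100, rid=900.0),
              make_measurement(1, area_px=100, rid=1100.0),
              make_measurement(2, area_px=100, rid=1000.0),
              make_measurement(3, area_px=100, rid=250.0)]  # fragment
        calls = classify_rois(ms, config)
        fr = field_summary(calls, ms)
        assert fr.average_cellular_dna == pytest.approx((900 + 1100 + 1000) / 3)

    def test_zero_retained_field(self):
        fr = field_summary([], [], slide_id="s", condition="pma", field_index=2)
        assert fr.n_total_retained == 0
        assert math.isnan(fr.average_cellular_dna)

    def test_slide_pooling_of_counts(self, config):
        fields = []
        for idx, (nets, retained) in enumerate([(2, 10), (3, 10)], start=1):
            ms = [make_measurement(i, area_px=500 if i < nets else 100,
                                   rid=1000.0) for i in range(retained)]
            calls = classify_rois(ms, config)
            fields.append(field_summary(calls, ms, slide_id="s1",
                                        condition="pma", field_index=idx))
        slide = slide_summary(fields, group="patients")
        assert slide.net_percent == pytest.approx(25.0)
        assert slide.total_retained == 20

    def test_single_clean_field_is_zero_percent(self, config):
        ms = [make_measurement(i, area_px=100, rid=1000.0) for i in range(50)]
        fr = field_summary(classify_rois(ms, config), ms)
        slide = slide_summary([fr])
        assert slide.net_percent == 0.0

    def test_pooling_is_field_order_invariant(self, config):
        fields = []
        for idx, (nets, n) in enumerate([(1, 5), (4, 20), (0, 8)], start=1):
            ms = [make_measurement(i, area_px=500 if i < nets else 100,
                                   rid=1000.0) for i in range(n)]
            fields.append(field_summary(classify_rois(ms, config), ms,
                                        slide_id="s", condition="c",
                                        field_index=idx))
        forward = slide_summary(fields).net_percent
        backward = slide_summary(fields[::-1]).net_percent
        assert forward == backward

    def test_zero_retained_slide_flagged(self):
        fr = field_summary([], [], slide_id="s", condition="c", field_index=1)
        slide = slide_summary([fr])
        assert math.isnan(slide.net_percent)
        assert "no_retained_rois" in slide.flags

    def test_mixed_slides_rejected(self, config):
        f1 = field_summary([], [], slide_id="a", condition="c", field_index=1)
        f2 = field_summary([], [], slide_id="b", condition="c", field_index=1)
        with pytest.raises(ValidationError):
            slide_summary([f1, f2])


class TestConfig:
    def test_cutoff_ordering_enforced(self):
        with pytest.raises(ValidationError):
            PipelineConfig(net_area_cutoff=1.0)
        with pytest.raises(ValidationError):
            PipelineConfig(upper_elim_cutoff=0.4, lower_elim_cutoff=0.5)

    def test_yaml_round_trip(self, tmp_path):
        import yaml
        cfg = PipelineConfig(net_area_cutoff=5.0)
        path = tmp_path / "c.yaml"
        path.write_text(yaml.safe_dump(cfg.to_dict()))
        again = PipelineConfig.from_yaml(path)
        assert again.net_area_cutoff == 5.0
        assert again.segmentation.phansalkar_radius == 15
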