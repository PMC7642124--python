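import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dicect.config import DEFAULT_ANATOMY, anatomy_for
from dicect.errors import CoverageError, LabelingError, RangeError
from dicect.profile_model import ExtractedRecord, SegmentStats
from dicect.stain_metrics import (ShrinkageResult, SliceMetrics,
                                  aggregate_whole_brain,
                                  compute_region_shrinkage,
                                  compute_slice_metrics, shrinkage_percent,
                                  summarize_shrinkage)
from dicect.datasets import reference_shrinkage_results


def seg(label, a, b, mean, iqr=0.0, n=10, strengths=(50.0, 50.0)):
    return SegmentStats(label=label, x_left_mm=a, x_right_mm=b,
                        edge_strength_left=strengths[0],
                        edge_strength_right=strengths[1],
                        mean_hu=mean, median_hu=mean, sd_hu=0.0, iqr_hu=iqr,
                        n_samples=n)


def record(segments, species="S", specimen="X", slc=2, t=0.0):
    positions = [segments[0].x_left_mm] + [s.x_right_mm for s in segments]
    strengths = [segments[0].edge_strength_left] + \
                [s.edge_strength_right for s in segments]
    return ExtractedRecord(species=species, specimen_id=specimen,
                           slice_index=slc, time_h=t,
                           edge_positions=tuple(positions),
                           edge_strengths=tuple(strengths),
                           segments=tuple(segments))


class TestSliceMetrics:
    def test_p2_pools_background_samples(self):
        rec = record([seg("background", 0.0, 1.0, 4.0),
                      seg("brain_tissue", 1.0, 3.0, 10.0),
                      seg("background", 3.0, 4.0, 6.0)])
        m = compute_slice_metrics(rec)
        assert m.p2 == pytest.approx(5.0)

    def test_unstained_flat_profile_has_no_contrast(self):
        rec = record([seg("background", 0.0, 1.0, 7.0),
                      seg("brain_tissue", 1.0, 3.0, 7.0),
                      seg("background", 3.0, 4.0, 7.0)])
        m = compute_slice_metrics(rec)
        assert m.p2 == pytest.approx(0.0)
        assert m.p3 == pytest.approx(0.0)

    def test_unequal_background_counts_are_weighted(self):
        rec = record([seg("background", 0.0, 1.0, 4.0, n=30),
                      seg("brain_tissue", 1.0, 3.0, 10.0),
                      seg("background", 3.0, 4.0, 8.0, n=10)])
        m = compute_slice_metrics(rec)
        assert m.p2 == pytest.approx(10.0 - (30 * 4.0 + 10 * 8.0) / 40)

    def test_shark_slice1_value_counts(self, noiseless_demo):
        """Three brain tissues on shark slice 1 give 6 P1 values, 3 widths."""
        _, series, _, records, _ = noiseless_demo
        rec = [r for r in records
               if r.species == "C_punctatum" and r.slice_index == 1][0]
        m = compute_slice_metrics(rec, series.anatomy("C_punctatum", 1))
        assert len(m.p1_values) == 6
        assert len(m.p4_widths) == 3
        assert len(m.pooled_widths) == 2  # anterior telencephalon excluded

    def test_nerve_segments_excluded_from_contrast(self):
        anatomy = anatomy_for("C_auratus", 4)
        segs = [seg("background", 0.0, 1.0, 5.0),
                seg("excluded_nerve", 1.0, 1.5, 50.0),
                seg("background", 1.5, 2.5, 5.0),
                seg("brain_tissue", 2.5, 4.5, 15.0, iqr=3.0),
                seg("background", 4.5, 5.5, 5.0),
                seg("excluded_nerve", 5.5, 6.0, 50.0),
                seg("background", 6.0, 7.0, 5.0)]
        m = compute_slice_metrics(record(segs, slc=4), anatomy)
        assert m.p2 == pytest.approx(10.0)  # nerves play no part
        assert m.p3_values == (3.0,)
        assert len(m.p1_values) == 2

    def test_labeling_errors(self):
        with pytest.raises(LabelingError, match="brain_tissue"):
            compute_slice_metrics(record([seg("background", 0, 1, 4.0),
                                          seg("background", 1, 2, 4.0)]))


class TestShrinkagePercent:
    @pytest.mark.parametrize("start,end,expected", [
        (5.46, 4.78, 100 * (5.46 - 4.78) / 5.46),  # = 12.4542...
        (3.0, 3.0, 0.0),
        (2.0, 2.2, -10.0),  # swelling keeps its sign
        (3.0, 2.7, 10.0),
    ])
    def test_formula(self, start, end, expected):
        assert shrinkage_percent(start, end) == pytest.approx(expected)

    def test_exact_on_relative_shrinkage(self):
        for w in (0.5, 2.38, 5.46):
            for s in (0.0, 0.07, 0.2):
                assert shrinkage_percent(w, w * (1 - s)) == pytest.approx(
                    100 * s, abs=1e-9)

    @settings(deadline=None, derandomize=True)
    @given(w=st.floats(0.01, 100.0), s=st.floats(0.0, 0.99))
    def test_relative_shrinkage_recovered_for_any_width(self, w, s):
        assert shrinkage_percent(w, w * (1 - s)) == pytest.approx(
            100.0 * s, abs=1e-6)

    def test_zero_start_is_domain_error(self):
        with pytest.raises(RangeError):
            shrinkage_percent(0.0, 1.0)


def slice_metric(species, specimen, slc, t, widths, p1=(100.0, 100.0),
                 p2=10.0, p3=(1.0,)):
    return SliceMetrics(species=species, specimen_id=specimen,
                        slice_index=slc, time_h=t, p1_values=tuple(p1),
                        p2=p2, p3_values=tuple(p3), p4_widths=tuple(widths),
                        pooled_widths=tuple(widths))


class TestRegionShrinkage:
    def test_simple_region(self):
        ms = [slice_metric("S", "X", 3, 0.0, (3.0,)),
              slice_metric("S", "X", 3, 96.0, (2.7,))]
        (res,) = compute_region_shrinkage(ms)
        assert res.region == "Cer"
        assert res.percent == pytest.approx(10.0)

    def test_reference_olfactory_bulb_cell(self):
        """Widths consistent with the published CP2 OBs value give 13.20%."""
        start = 5.0
        end = start * (1 - 0.1320)
        ms = [slice_metric("C_punctatum", "CP2", 1, 0.0, (start,)),
              slice_metric("C_punctatum", "CP2", 1, 240.0, (end,))]
        (res,) = compute_region_shrinkage(ms)
        assert res.region == "OBs"
        assert res.percent == pytest.approx(13.20, abs=1e-9)

    def test_missing_endpoint_time(self):
        ms = [slice_metric("S", "X", 3, 0.0, (3.0,))]
        with pytest.raises(CoverageError):
            compute_region_shrinkage(ms)


class TestWholeBrainAggregation:
    def test_across_slice_mean(self):
        ms = [slice_metric("S", "X", s, 0.0, (1.0,), p1=(float(s),))
              for s in (1, 2, 3, 4)]
        wb = aggregate_whole_brain(ms)
        assert wb.table.loc[0.0, "mean_p1"] == pytest.approx(2.5)

    def test_two_stage_mean_differs_from_pooled(self):
        """Per-slice means first: (6,2,2,2) -> 3.0, not the pooled 4.0."""
        ms = [slice_metric("S", "X", 1, 0.0, (1.0,), p1=(6.0,) * 6)]
        ms += [slice_metric("S", "X", s, 0.0, (1.0,), p1=(2.0, 2.0))
               for s in (2, 3, 4)]
        wb = aggregate_whole_brain(ms)
        assert wb.table.loc[0.0, "mean_p1"] == pytest.approx(3.0)

    def test_missing_slice_named(self):
        ms = [slice_metric("S", "X", s, 0.0, (1.0,)) for s in (1, 2, 3, 4)]
        ms += [slice_metric("S", "X", s, 24.0, (1.0,)) for s in (1, 2, 4)]
        with pytest.raises(CoverageError, match="slice 3"):
            aggregate_whole_brain(ms)

    def test_offset_and_scale_behaviour(self):
        """+c leaves P1/P3/P4 and P2 unchanged; xc scales P1-P3."""
        base = slice_metric("S", "X", 2, 0.0, (2.0,), p1=(10.0, 12.0),
                            p2=5.0, p3=(3.0,))
        scaled = slice_metric("S", "X", 2, 0.0, (2.0,),
                              p1=(30.0, 36.0), p2=15.0, p3=(9.0,))
        assert scaled.p3 == pytest.approx(3.0 * base.p3)
        assert scaled.p4_widths == base.p4_widths


class TestSummarizeShrinkage:
    def test_reference_table_arithmetic(self):
        """Summary over the published per-specimen cells reproduces the
        published region means and the flat overall means/SDs."""
        df = summarize_shrinkage(reference_shrinkage_results())
        def cell(species, region, col):
            row = df[(df.species == species) & (df.region == region)]
            return float(row[col].iloc[0])

        assert cell("C_punctatum", "Tel", "mean_percent") == pytest.approx(
            12.52, abs=0.005)
        assert cell("C_punctatum", "Cer", "mean_percent") == pytest.approx(
            10.73, abs=0.005)
        assert cell("C_auratus", "OBs", "mean_percent") == pytest.approx(
            8.83, abs=0.005)
        assert cell("C_auratus", "Med", "mean_percent") == pytest.approx(
            18.83, abs=0.005)
        assert cell("C_punctatum", "Overall", "mean_percent") == \
            pytest.approx(13.54, abs=0.005)
        assert cell("C_punctatum", "Overall", "sd_percent") == \
            pytest.approx(4.75, abs=0.005)
        assert cell("C_auratus", "Overall", "mean_percent") == \
            pytest.approx(17.77, abs=0.005)
        assert cell("C_auratus", "Overall", "sd_percent") == \
            pytest.approx(7.25, abs=0.005)

    def test_overall_is_flat_mean_not_mean_of_region_means(self):
        results = [
            ShrinkageResult("S", "A", "OBs", 1.0, 0.90),  # 10%
            ShrinkageResult("S", "B", "OBs", 1.0, 0.80),  # 20%
            ShrinkageResult("S", "A", "Tel", 1.0, 0.70),  # 30%
        ]
        df = summarize_shrinkage(results)
        overall = df[df.region == "Overall"]
        assert float(overall["mean_percent"].iloc[0]) == pytest.approx(20.0)
        # mean of region means would be (15 + 30) / 2 = 22.5

    def test_single_value_has_no_sd(self):
        df = summarize_shrinkage([ShrinkageResult("S", "A", "Cer", 2.0, 1.8)])
        row = df[df.region == "Cer"].iloc[0]
        assert row["mean_percent"] == pytest.approx(10.0)
        assert math.isnan(row["sd_percent"])
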