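"""Callset comparison, truth assignment, metrics and discrepancy reasons."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from panelval.callset import VariantAnnotation, VariantCall
from panelval.concordance import (ComparisonResult, assign_discrepancy_reason,
                                  assign_truth, compare_callsets,
                                  concordance_metrics, detection_rate,
                                  round_half_up, specificity, venn_summary)
from panelval.coverage import DepthTrack


def call(pos, platform, sample_id="S1", alt="T", filter_pass=True, **ann_kw):
    return VariantCall("chr1", pos, "C", alt, 50, 0.5, filter_pass, platform,
                       sample_id, VariantAnnotation(**ann_kw))


def key(pos, alt="T"):
    return ("chr1", pos, "C", alt)


def flat_track(sample_id, platform, depth, span=2000):
    pos = np.arange(span)
    return DepthTrack(sample_id, platform,
                      {"chr1": (pos, np.full(span, depth, dtype=np.int64))})


class TestCompareCallsets:
    def test_identical_callsets(self):
        ts = [call(1, "TS"), call(2, "TS")]
        wes = [call(1, "WES"), call(2, "WES")]
        cmp = compare_callsets(ts, wes)
        assert cmp.shared == {key(1), key(2)}
        assert not cmp.ts_only and not cmp.wes_only

    def test_disjoint_callsets(self):
        cmp = compare_callsets([call(1, "TS")], [call(2, "WES")])
        assert not cmp.shared
        assert cmp.ts_only == {key(1)} and cmp.wes_only == {key(2)}

    def test_same_position_different_alt_not_shared(self):
        cmp = compare_callsets([call(1, "TS", alt="T")], [call(1, "WES", alt="G")])
        assert not cmp.shared and len(cmp.all_keys) == 2

    @given(st.sets(st.integers(1, 60), max_size=25),
           st.sets(st.integers(1, 60), max_size=25))
    @settings(max_examples=100, deadline=None)
    def test_partition_sum_rule(self, ts_pos, wes_pos):
        cmp = compare_callsets([call(p, "TS") for p in ts_pos],
                               [call(p, "WES") for p in wes_pos])
        assert len(cmp.shared) + len(cmp.ts_only) + len(cmp.wes_only) == \
            len(ts_pos | wes_pos)
        assert cmp.shared == {key(p) for p in ts_pos & wes_pos}


class TestAssignTruth:
    def test_states(self):
        cmp = compare_callsets(
            [call(1, "TS"), call(2, "TS"), call(3, "TS"), call(4, "TS")],
            [call(1, "WES"), call(5, "WES")])
        with pytest.warns(UserWarning, match="lack a confirmation"):
            assign_truth(cmp, {key(2): True, key(3): False, key(5): True})
        assert cmp.truth[key(1)] == "true_shared"
        assert cmp.truth[key(2)] == "true_confirmed"
        assert cmp.truth[key(3)] == "false_unconfirmed"
        assert cmp.truth[key(4)] == "untested"
        assert cmp.truth[key(5)] == "true_confirmed"


class TestMetrics:
    def build(self, n_shared, ts_conf, ts_unconf, wes_conf, wes_unconf=0):
        shared = {key(i) for i in range(1, n_shared + 1)}
        base = n_shared
        ts_only = {key(base + i) for i in range(1, ts_conf + ts_unconf + 1)}
        base += ts_conf + ts_unconf
        wes_only = {key(base + i) for i in range(1, wes_conf + wes_unconf + 1)}
        sanger = {}
        for i, k in enumerate(sorted(ts_only)):
            sanger[k] = i < ts_conf
        for i, k in enumerate(sorted(wes_only)):
            sanger[k] = i < wes_conf
        cmp = ComparisonResult(shared=shared, ts_only=ts_only, wes_only=wes_only)
        return assign_truth(cmp, sanger)

    def test_perfect_platform(self):
        cmp = self.build(5, 0, 0, 0)
        assert detection_rate(cmp, "TS") == 100.0
        assert specificity(cmp, "TS") == 100.0

    def test_study_shaped_counts(self):
        cmp = self.build(89, 4, 2, 3)
        m = concordance_metrics(cmp)
        assert (m.detection_rate_ts, m.detection_rate_wes) == (96.9, 95.8)
        assert (m.specificity_ts, m.specificity_wes) == (97.9, 100.0)
        assert m.n_true == 96

    def test_zero_true_errors(self):
        cmp = self.build(0, 0, 1, 0)
        with pytest.raises(ValueError, match="zero true"):
            detection_rate(cmp, "TS")

    def test_removing_false_call_never_decreases_specificity(self):
        before = specificity(self.build(10, 2, 2, 1), "TS")
        after = specificity(self.build(10, 2, 1, 1), "TS")
        assert after >= before

    def test_specificity_100_when_no_false_calls(self):
        cmp = self.build(7, 3, 0, 2)
        assert specificity(cmp, "TS") == 100.0
        assert specificity(cmp, "WES") == 100.0


class TestVennSummary:
    def test_all_variant_decomposition(self):
        cmp = ComparisonResult(
            shared={key(i) for i in range(288)},
            ts_only={key(1000 + i) for i in range(66)},
            wes_only={key(2000 + i) for i in range(20)})
        out = venn_summary(cmp)
        assert out["counts"] == {"both": 288, "ts_only": 66, "wes_only": 20,
                                 "total": 374}
        assert out["percentages"] == {"both": 77, "ts_only": 18, "wes_only": 5}

    def test_true_hfi_decomposition(self):
        cmp = ComparisonResult(
            shared={key(i) for i in range(89)},
            ts_only={key(1000 + i) for i in range(6)},
            wes_only={key(2000 + i) for i in range(3)})
        sanger = {k: True for k in cmp.ts_only | cmp.wes_only}
        for i, k in enumerate(sorted(cmp.ts_only)):
            if i < 2:
                sanger[k] = False
        assign_truth(cmp, sanger)
        out = venn_summary(cmp, true_only=True)
        assert out["counts"] == {"both": 89, "ts_only": 4, "wes_only": 3,
                                 "total": 96}
        assert out["percentages"] == {"both": 93, "ts_only": 4, "wes_only": 3}

    def test_empty_comparison(self):
        out = venn_summary(ComparisonResult(set(), set(), set()))
        assert out["counts"]["total"] == 0
        assert out["percentages"] == {"both": 0, "ts_only": 0, "wes_only": 0}


class TestRounding:
    @pytest.mark.parametrize("x,nd,expected", [
        (92.708, 0, 93.0), (96.875, 1, 96.9), (95.833, 1, 95.8),
        (97.894, 1, 97.9), (0.5, 0, 1.0), (2.5, 0, 3.0), (1.25, 1, 1.3),
    ])
    def test_half_up(self, x, nd, expected):
        assert round_half_up(x, nd) == expected


class TestDiscrepancyReasons:
    def setup_cmp(self, ts_pos=(100,), wes_pos=(), sanger=None):
        ts = [call(p, "TS") for p in ts_pos]
        wes = [call(p, "WES") for p in wes_pos]
        cmp = compare_callsets(ts, wes)
        return assign_truth(cmp, sanger or {key(p): True for p in
                                            set(ts_pos) ^ set(wes_pos)})

    def test_coverage_reason_on_zero_depth(self):
        cmp = self.setup_cmp()
        ts_tracks = {"S1": flat_track("S1", "TS", 500)}
        wes_tracks = {"S1": flat_track("S1", "WES", 0)}
        reason = assign_discrepancy_reason(key(100), cmp, ts_tracks, wes_tracks)
        assert reason == "insufficient_coverage_other_platform"

    def test_missing_track_counts_as_zero_depth(self):
        cmp = self.setup_cmp()
        reason = assign_discrepancy_reason(key(100), cmp, {}, {})
        assert reason == "insufficient_coverage_other_platform"

    def test_filter_fail_reason(self):
        raw = [call(100, "TS"), call(100, "WES", filter_pass=False)]
        cmp = self.setup_cmp()
        ts_tracks = {"S1": flat_track("S1", "TS", 500)}
        wes_tracks = {"S1": flat_track("S1", "WES", 300)}
        reason = assign_discrepancy_reason(key(100), cmp, ts_tracks, wes_tracks, raw)
        assert reason == "pipeline_filter_fail"

    def test_misalignment_reason_for_unconfirmed_gc_rich(self):
        raw = [call(100, "TS", gc_content_pct=75.0)]
        cmp = self.setup_cmp(sanger={key(100): False})
        ts_tracks = {"S1": flat_track("S1", "TS", 500)}
        wes_tracks = {"S1": flat_track("S1", "WES", 275)}
        reason = assign_discrepancy_reason(key(100), cmp, ts_tracks, wes_tracks, raw)
        assert reason == "false_positive_misalignment"

    def test_repeat_flag_also_triggers_misalignment(self):
        raw = [call(100, "TS", gc_content_pct=50.0, repeat_flag=True)]
        cmp = self.setup_cmp(sanger={key(100): False})
        tracks = {"S1": flat_track("S1", "TS", 500)}
        wtracks = {"S1": flat_track("S1", "WES", 54)}
        reason = assign_discrepancy_reason(key(100), cmp, tracks, wtracks, raw)
        assert reason == "false_positive_misalignment"

    def test_confirmed_gc_rich_stays_unexplained(self):
        # confirmed variants never get the misalignment label
        raw = [call(100, "TS", gc_content_pct=80.0)]
        cmp = self.setup_cmp(sanger={key(100): True})
        tracks = {"S1": flat_track("S1", "TS", 500)}
        wtracks = {"S1": flat_track("S1", "WES", 300)}
        reason = assign_discrepancy_reason(key(100), cmp, tracks, wtracks, raw)
        assert reason == "unexplained"

    def test_reason_threshold_reclassifies_borderline_depth(self):
        # a WES-only variant whose TS depth is 15x: above the 10x calling
        # cutoff so unexplained by default, insufficient coverage at 20x
        cmp = self.setup_cmp(ts_pos=(), wes_pos=(100,))
        tracks = {"S1": flat_track("S1", "TS", 15)}
        wtracks = {"S1": flat_track("S1", "WES", 165)}
        default = assign_discrepancy_reason(key(100), cmp, tracks, wtracks)
        stricter = assign_discrepancy_reason(key(100), cmp, tracks, wtracks,
                                             reason_depth_threshold=20)
        assert default == "unexplained"
        assert stricter == "insufficient_coverage_other_platform"

    def test_shared_variant_rejected(self):
        cmp = self.setup_cmp(ts_pos=(100,), wes_pos=(100,), sanger={})
        with pytest.raises(ValueError, match="platform-unique"):
            assign_discrepancy_reason(key(100), cmp, {}, {})
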