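"""Two-stage infarct detection: benchmark flagging, H-spread, and the
Infarction Condition."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tagstrain as ts
from tagstrain.detection import (
    DEFAULT_ALPHAS,
    BenchmarkTable,
    SegmentSeries,
    classify,
    flag_potential,
    healthy_reference,
    hspread,
)
from tagstrain.strain import SLICE_SEGMENT_IDS


def brute_force_iqr(values):
    """Independent IQR oracle: manual sort + linear interpolation of order
    statistics (no numpy quantile machinery)."""
    v = sorted(float(x) for x in values)
    n = len(v)

    def q(p):
        h = p * (n - 1)
        lo = int(np.floor(h))
        hi = min(lo + 1, n - 1)
        return v[lo] + (h - lo) * (v[hi] - v[lo])

    return q(0.75) - q(0.25)


def series_with_hspread(sid, level, h, n=4):
    """A segment series whose H-spread is exactly ``h`` (starts at 0)."""
    return SegmentSeries(sid, level, np.array([0.0, h, 0.0, h]))


def lv_series(es_by_segment=None, h_by_segment=None):
    """Build all 16 segment series; healthy defaults are strongly
    contracting (ES -0.30) with healthy-sized spread."""
    series = {}
    for level, ids in SLICE_SEGMENT_IDS.items():
        for sid in ids:
            es = (es_by_segment or {}).get(sid, -0.30)
            h = (h_by_segment or {}).get(sid, None)
            if h is None:
                s_f = np.linspace(0.0, es, 8)
            else:
                s_f = np.array([0.0, h, 0.0, h, 0.0, h, 0.0, es])
                # keep last element as ES while preserving IQR roughly; use
                # the exact construction when ES doesn't disturb quartiles
                s_f = np.array([0.0, h, 0.0, h, 0.0, h, 0.0, es])
            series[sid] = SegmentSeries(sid, level, s_f)
    return series


class TestHspread:
    def test_constant_series_zero(self):
        assert hspread(np.full(8, 3.7)) == 0.0

    def test_four_point_oracle(self):
        # linear interpolation of order statistics: Q3 - Q1 = 3.25 - 1.75
        assert hspread(np.array([1.0, 2.0, 3.0, 4.0])) == pytest.approx(1.5, abs=1e-12)

    def test_matches_brute_force_on_random_series(self):
        rng = np.random.default_rng(12)
        for _ in range(1000):
            n = int(rng.integers(4, 16))
            v = rng.normal(size=n)
            assert hspread(v) == pytest.approx(brute_force_iqr(v), abs=1e-12)

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError):
            hspread(np.array([0.1]))

    def test_phantom_healthy_exceeds_akinetic(self, infarcted_lv):
        lv, report, series = infarcted_lv
        healthy = [s for sid, s in series.items() if sid not in lv.infarcted_segments]
        akinetic = [s for sid, s in series.items() if sid in lv.infarcted_segments]
        assert min(hspread(s) for s in healthy) > max(hspread(s) for s in akinetic)


class TestBenchmarkTable:
    def test_printed_values(self):
        bt = BenchmarkTable.default()
        assert bt.lookup("basal", "anterior") == (-0.20, 0.03)
        assert bt.lookup("apical", "inferior") == (-0.23, 0.04)

    def test_apical_merged_sectors(self):
        bt = BenchmarkTable.default()
        assert bt.lookup("apical", "septal") == (-0.18, 0.03)
        assert bt.lookup("apical", "lateral") == (-0.24, 0.04)

    def test_all_means_negative_all_sds_positive(self):
        bt = BenchmarkTable.default()
        for sid in range(1, 17):
            mean, sd = bt.lookup_segment(sid)
            assert mean < 0 and sd > 0

    def test_missing_entry_raises(self):
        bt = BenchmarkTable.default()
        with pytest.raises(KeyError):
            bt.lookup("basal", "apex-cap")


class TestFlagPotential:
    bt = BenchmarkTable.default()

    def flag(self, es):
        # segment 1 = basal anterior, benchmark mean -0.20
        return flag_potential(SegmentSeries(1, "basal", np.array([0.0, es])), self.bt)

    def test_strong_contraction_not_flagged(self):
        assert self.flag(-0.25) is False

    def test_weak_contraction_flagged(self):
        assert self.flag(-0.10) is True

    def test_boundary_equality_not_flagged(self):
        assert self.flag(-0.20) is False  # strict inequality

    def test_sd_margin_option(self):
        # with a 1-SD margin the threshold drops to |mean| - SD = 0.17
        s = SegmentSeries(1, "basal", np.array([0.0, -0.18]))
        assert flag_potential(s, self.bt, margin_sd=0.0) is True
        assert flag_potential(s, self.bt, margin_sd=1.0) is False


class TestHealthyReference:
    def test_worked_example_same_slice_mean(self):
        """Basal flags on 1, 2; reference is the mean H-spread of the
        remaining basal segments 3-6: mean(0.08, 0.10, 0.09, 0.13) = 0.10."""
        series = {}
        for sid, h in zip([1, 2, 3, 4, 5, 6], [0.02, 0.03, 0.08, 0.10, 0.09, 0.13]):
            series[sid] = series_with_hspread(sid, "basal", h)
        flags = {sid: sid in (1, 2) for sid in series}
        refs, notes = healthy_reference(series, flags)
        assert set(refs) == {1, 2}
        for sid in (1, 2):
            h_ref, source = refs[sid]
            assert h_ref == pytest.approx(0.10, abs=1e-12)
            assert source == "H_healthy_basal"
        assert notes == []

    def test_fully_flagged_slice_falls_back_to_whole_lv(self):
        series = {}
        for level, ids in SLICE_SEGMENT_IDS.items():
            for sid in ids:
                series[sid] = series_with_hspread(sid, level, 0.10)
        flags = {sid: sid >= 13 for sid in series}  # whole apical slice flagged
        refs, notes = healthy_reference(series, flags)
        for sid in (13, 14, 15, 16):
            h_ref, source = refs[sid]
            assert source == "H_healthy_all"
            assert h_ref == pytest.approx(0.10)
        assert any("whole LV" in n for n in notes)

    def test_no_flags_empty_output(self):
        series = {1: series_with_hspread(1, "basal", 0.1)}
        refs, notes = healthy_reference(series, {1: False})
        assert refs == {} and notes == []


class TestClassify:
    def run_two_segment_slice(self, h_seg, h_others, alpha):
        """Flagged basal segment with given H against 5 unflagged ones."""
        es = {1: -0.05}  # weak -> flagged; others strong
        hmap = {1: h_seg, 2: h_others, 3: h_others, 4: h_others, 5: h_others,
                6: h_others}
        series = {}
        for level, ids in SLICE_SEGMENT_IDS.items():
            for sid in ids:
                es_v = es.get(sid, -0.30)
                h = hmap.get(sid, 0.10)
                s_f = np.array([0.0, h, 0.0, h, 0.0, h, 0.0, es_v])
                series[sid] = SegmentSeries(sid, level, s_f)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return classify(series, alphas={"basal": alpha})

    def test_reduction_above_alpha_is_infarcted(self):
        report = self.run_two_segment_slice(h_seg=0.05, h_others=0.10, alpha=30.0)
        res = report.segments[1]
        assert res.potentially_infarcted and res.infarcted
        assert res.reduction_pct == pytest.approx(50.0, abs=1e-6)

    def test_reduction_below_alpha_stays_healthy(self):
        report = self.run_two_segment_slice(h_seg=0.08, h_others=0.10, alpha=30.0)
        res = report.segments[1]
        assert res.potentially_infarcted and not res.infarcted
        assert res.reduction_pct == pytest.approx(20.0, abs=1e-6)

    def test_default_alphas(self):
        assert DEFAULT_ALPHAS == {"basal": 30.0, "midventricular": 30.0,
                                  "apical": 20.0}

    def test_unflagged_segments_have_zero_reduction(self):
        report = self.run_two_segment_slice(0.05, 0.10, 30.0)
        for sid, res in report.segments.items():
            if not res.potentially_infarcted:
                assert res.reduction_pct == 0.0
                assert not res.infarcted

    def test_infarcted_implies_flagged(self):
        report = self.run_two_segment_slice(0.05, 0.10, 30.0)
        for res in report.segments.values():
            assert (not res.infarcted) or res.potentially_infarcted

    @given(
        h_seg=st.floats(0.001, 0.2),
        h_others=st.floats(0.001, 0.2),
        a1=st.floats(1.0, 100.0),
        a2=st.floats(1.0, 100.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_alpha(self, h_seg, h_others, a1, a2):
        """Raising alpha can only shrink the infarcted set."""
        lo, hi = sorted([a1, a2])
        r_lo = self.run_two_segment_slice(h_seg, h_others, lo)
        r_hi = self.run_two_segment_slice(h_seg, h_others, hi)
        assert set(r_hi.infarcted_ids) <= set(r_lo.infarcted_ids)

    def test_all_sixteen_flagged_degenerate(self):
        series = {}
        for level, ids in SLICE_SEGMENT_IDS.items():
            for sid in ids:
                series[sid] = SegmentSeries(sid, level,
                                            np.array([0.0, 0.01, 0.0, -0.02]))
        with pytest.warns(UserWarning, match="all 16"):
            report = classify(series)
        assert report.infarcted_ids == list(range(1, 17))

    def test_zero_reference_degenerate(self):
        # flagged segment whose reference segments all have zero spread
        series = {}
        for level, ids in SLICE_SEGMENT_IDS.items():
            for sid in ids:
                if sid == 1:
                    s_f = np.full(4, -0.01)  # flagged (weak), H = 0
                elif level == "basal":
                    s_f = np.full(4, -0.30)  # unflagged (strong), H = 0
                else:
                    s_f = np.array([0.0, -0.1, -0.2, -0.30])
                series[sid] = SegmentSeries(sid, level, s_f)
        with pytest.warns(UserWarning, match="reference H-spread is 0"):
            report = classify(series)
        assert not report.segments[1].infarcted
        assert np.isnan(report.segments[1].reduction_pct)

    def test_phantom_recovers_ground_truth(self, infarcted_lv):
        """Clean 3-slice phantom with contiguous contractility-0.2
        territories: defaults recover exactly the true infarcted set."""
        lv, report, _ = infarcted_lv
        assert report.infarcted_ids == sorted(lv.infarcted_segments)
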