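"""Segment selection, extraction and channel QC."""

from __future__ import annotations

import math

import numpy as np
import pytest

from normkit.io import Recording
from normkit.synth import generate_signal
from normkit.temporal import (
    ExamTimeline,
    FlagRules,
    SegmentRecord,
    SeizureEvent,
    SelectionPolicy,
    extract_segment,
    flag_unsuitable_channels,
    intersect_intervals,
    normalize_intervals,
    remove_seizure_buffer,
    select_segments,
    state_periods,
    subtract_intervals,
    suitable_periods,
    total_duration,
)

H = 3600.0


def _contains(intervals, t):
    return any(a <= t < b for a, b in intervals)


class TestIntervalArithmetic:
    def test_normalize_merges_and_sorts(self):
        assert normalize_intervals([(5, 7), (0, 3), (2, 4)]) == [(0, 4), (5, 7)]

    def test_subtract_splits(self):
        assert subtract_intervals([(0, 10)], [(3, 5)]) == [(0, 3), (5, 10)]

    def test_intersect(self):
        assert intersect_intervals([(0, 5), (8, 12)], [(4, 9)]) == [(4, 5), (8, 9)]

    @pytest.mark.parametrize("seed", range(5))
    def test_subtract_pointwise_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = normalize_intervals(
            (s, s + d) for s, d in zip(rng.uniform(0, 90, 6), rng.uniform(1, 15, 6))
        )
        b = normalize_intervals(
            (s, s + d) for s, d in zip(rng.uniform(0, 90, 6), rng.uniform(1, 15, 6))
        )
        result = subtract_intervals(a, b)
        for t in np.linspace(0, 110, 2201):
            assert _contains(result, t) == (_contains(a, t) and not _contains(b, t))


class TestStatePeriods:
    def test_all_wake_with_skip(self):
        tl = ExamTimeline(state_intervals=[(0, 48 * H, "W")])
        out = state_periods(tl, SelectionPolicy())
        assert out == [(24 * H, 48 * H)]

    def test_missing_state_empty(self):
        tl = ExamTimeline(state_intervals=[(0, 48 * H, "W")])
        assert state_periods(tl, SelectionPolicy(state="N3")) == []

    def test_time_of_day_window(self):
        tl = ExamTimeline(
            state_intervals=[(0, 48 * H, "W")], exam_start="2024-01-01T08:00:00"
        )
        policy = SelectionPolicy(time_of_day_window=("08:00", "22:00"))
        out = state_periods(tl, policy)
        # exam starts 08:00; skip ends at 08:00 next day
        assert out[0] == (24 * H, 38 * H)
        for a, b in out:
            for t in (a, (a + b) / 2, b - 1):
                clock = (8 + t / H) % 24
                assert 8 <= clock < 22

    @pytest.mark.parametrize("seed", range(10))
    def test_randomized_per_second_oracle(self, seed):
        rng = np.random.default_rng(seed)
        bounds = np.sort(rng.uniform(0, 100 * H, 7))
        states = rng.choice(["W", "N2", "N3"], size=8)
        edges = [0.0, *bounds, 100 * H]
        tl = ExamTimeline(
            state_intervals=[
                (edges[i], edges[i + 1], states[i]) for i in range(8)
                if edges[i + 1] > edges[i]
            ]
        )
        policy = SelectionPolicy()
        out = state_periods(tl, policy)
        probes = rng.uniform(0, 100 * H, 500)
        for t in probes:
            in_state = any(a <= t < b and s == "W" for a, b, s in tl.state_intervals)
            expected = in_state and t >= 24 * H
            assert _contains(out, t) == expected


class TestSeizureBuffer:
    def test_no_seizures_identity(self):
        ivs = [(0.0, 10 * H)]
        assert remove_seizure_buffer(ivs, [], 2 * H) == ivs

    def test_worked_example(self):
        out = remove_seizure_buffer(
            [(0.0, 10 * H)],
            [SeizureEvent(onset=5 * H, duration=60.0, type="focal")],
            2 * H,
        )
        assert out == [(0.0, 3 * H), (7 * H + 60.0, 10 * H)]

    def test_buffer_swallows_everything(self):
        out = remove_seizure_buffer(
            [(0.0, 4 * H)], [SeizureEvent(onset=2 * H, type="focal")], 10 * H
        )
        assert out == []

    def test_unknown_type_rejected(self):
        with pytest.raises(ValueError, match="unknown seizure type"):
            remove_seizure_buffer([(0, 10)], [SeizureEvent(onset=5, type="weird")], 1.0)

    def test_per_type_buffers(self):
        seizures = [
            SeizureEvent(onset=10 * H, type="focal"),
            SeizureEvent(onset=30 * H, type="subclin"),
        ]
        out = remove_seizure_buffer(
            [(0.0, 40 * H)], seizures, {"focal": 4 * H, "subclin": 2 * H, "sg": 4 * H}
        )
        assert out == [(0.0, 6 * H), (14 * H, 28 * H), (32 * H, 40 * H)]

    def test_missing_type_in_mapping_rejected(self):
        with pytest.raises(ValueError, match="no buffer"):
            remove_seizure_buffer(
                [(0, 10 * H)], [SeizureEvent(onset=5 * H, type="sg")], {"focal": H}
            )

    @pytest.mark.parametrize("seed", range(5))
    def test_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        ivs = normalize_intervals(
            (s, s + d) for s, d in zip(rng.uniform(0, 90 * H, 5), rng.uniform(H, 20 * H, 5))
        )
        seizures = [
            SeizureEvent(onset=float(o), duration=60.0, type="focal")
            for o in rng.uniform(0, 100 * H, 4)
        ]
        once = remove_seizure_buffer(ivs, seizures, 2 * H)
        twice = remove_seizure_buffer(once, seizures, 2 * H)
        assert once == twice
        assert total_duration(once) <= total_duration(ivs)


class TestSelectSegments:
    def test_greedy_hand_trace(self):
        out = select_segments([(0.0, 10 * H)], SelectionPolicy())
        assert out == [0.0, 4 * H, 8 * H]

    def test_infeasible_returns_fewer(self):
        out = select_segments([(0.0, 3 * H)], SelectionPolicy())
        assert out == [0.0]

    def test_empty_intervals(self):
        assert select_segments([], SelectionPolicy()) == []

    @pytest.mark.parametrize("seed", range(20))
    def test_constraint_checker_oracle(self, seed):
        rng = np.random.default_rng(seed)
        ivs = normalize_intervals(
            (s, s + d)
            for s, d in zip(rng.uniform(0, 80 * H, 6), rng.uniform(100, 12 * H, 6))
        )
        policy = SelectionPolicy(n_segments=int(rng.integers(1, 5)))
        out = select_segments(ivs, policy)
        assert len(out) <= policy.n_segments
        for start in out:
            assert any(a <= start and start + policy.segment_length <= b for a, b in ivs)
        for s1, s2 in zip(out, out[1:]):
            assert s2 - s1 >= policy.min_separation * H - 1e-9

    def test_gap_separation_mode(self):
        policy = SelectionPolicy(separation_mode="gap")
        out = select_segments([(0.0, 10 * H)], policy)
        for s1, s2 in zip(out, out[1:]):
            assert s2 - (s1 + policy.segment_length) >= policy.min_separation * H - 1e-9


class TestExtractSegment:
    def _recording(self, fs=256.0, duration=200.0, n_ch=4, offset=0.0):
        rng = np.random.default_rng(0)
        return Recording(
            data=rng.normal(size=(n_ch, int(duration * fs))),
            fs=fs,
            channel_names=[f"C{i}" for i in range(n_ch)],
            exam_offset=offset,
        )

    def test_sample_count(self):
        rec = self._recording()
        seg = extract_segment(
            rec, 10.0, SelectionPolicy(), subject_id="SYNH_001",
            hospital="SYNH", segment_number=1,
        )
        assert seg.data.shape == (4, 17920)  # 70 s * 256 Hz
        assert seg.duration == 70.0

    def test_exam_offset_respected(self):
        rec = self._recording(offset=1000.0)
        seg = extract_segment(
            rec, 1010.0, SelectionPolicy(), subject_id="S", hospital="H",
            segment_number=1,
        )
        np.testing.assert_array_equal(seg.data, rec.data[:, 2560 : 2560 + 17920])

    def test_out_of_range_rejected(self):
        rec = self._recording(duration=60.0)
        with pytest.raises(IndexError):
            extract_segment(
                rec, 10.0, SelectionPolicy(), subject_id="S", hospital="H",
                segment_number=1,
            )

    def test_round_trip(self, tmp_path):
        rec = self._recording()
        seg = extract_segment(
            rec, 0.0, SelectionPolicy(), subject_id="SYNH_002", hospital="SYNH",
            segment_number=2, spiking_channel_names=["C1"],
        )
        seg.unsuitable_channel_names = ["C3"]
        seg.save(tmp_path / "seg.h5")
        back = SegmentRecord.load(tmp_path / "seg.h5")
        np.testing.assert_array_equal(back.data, seg.data)
        assert back.metadata() == seg.metadata()

    def test_subset(self):
        rec = self._recording()
        seg = extract_segment(
            rec, 0.0, SelectionPolicy(), subject_id="S", hospital="H",
            segment_number=1, spiking_channel_names=["C1", "C2"],
        )
        sub = seg.subset(["C2", "C0"])
        assert sub.channel_names == ["C2", "C0"]
        np.testing.assert_array_equal(sub.data[1], seg.data[0])
        assert sub.spiking_channel_names == ["C2"]


def _make_segment(data, fs=256.0):
    data = np.asarray(data, dtype=float)
    return SegmentRecord(
        channel_names=[f"C{i}" for i in range(data.shape[0])],
        data=data,
        fs=fs,
        start_datetime="2024-01-01T10:00:00",
        duration=data.shape[1] / fs,
        wake_status="W",
        subject_id="SYNH_001",
        hospital="SYNH",
        segment_number=1,
    )


class TestFlagUnsuitableChannels:
    def _clean_data(self, n_ch=11, seed=0, duration=30.0, fs=256.0):
        return generate_signal(
            {"delta": 0.3, "theta": 0.25, "alpha": 0.2, "beta": 0.15, "gamma": 0.1},
            duration, fs, line_noise_hz=50.0, seed=seed, n_channels=n_ch,
        )

    def test_power_outlier_flagged(self):
        data = self._clean_data()
        data[4] *= 10.0  # 100x variance
        seg = _make_segment(data)
        assert flag_unsuitable_channels(seg) == ["C4"]
        assert seg.unsuitable_channel_names == ["C4"]

    def test_homogeneous_channels_unflagged(self):
        seg = _make_segment(self._clean_data())
        assert flag_unsuitable_channels(seg) == []

    def test_flatline_flagged(self):
        data = self._clean_data()
        data[7] = 1.5
        seg = _make_segment(data)
        assert "C7" in flag_unsuitable_channels(seg)

    def test_non_1f_spectrum_flagged(self):
        data = self._clean_data()
        # replace with flat-spectrum noise at matched variance
        rng = np.random.default_rng(3)
        data[2] = rng.normal(scale=data[2].std(), size=data.shape[1])
        seg = _make_segment(data)
        assert "C2" in flag_unsuitable_channels(seg)

    def test_single_channel_rejected(self):
        seg = _make_segment(self._clean_data(n_ch=1))
        with pytest.raises(ValueError, match="at least 2 channels"):
            flag_unsuitable_channels(seg)

    def test_flags_are_unioned(self):
        data = self._clean_data()
        seg = _make_segment(data)
        seg.unsuitable_channel_names = ["C0"]
        flag_unsuitable_channels(seg)
        assert "C0" in seg.unsuitable_channel_names


class TestSuitablePeriodsEndToEnd:
    def test_fs_floor_excludes(self):
        tl = ExamTimeline(
            state_intervals=[(0, 72 * H, "W")],
            fs_intervals=[(0, 36 * H, 128.0), (36 * H, 72 * H, 256.0)],
        )
        out = suitable_periods(tl, SelectionPolicy())
        assert out == [(36 * H, 72 * H)]

    def test_short_pieces_dropped(self):
        tl = ExamTimeline(
            state_intervals=[(0, 25 * H, "W"), (25 * H, 25 * H + 30, "N2"),
                             (25 * H + 30, 48 * H, "W")],
            fs_intervals=[(0, 48 * H, 256.0)],
        )
        policy = SelectionPolicy(segment_length=7200.0)
        for a, b in suitable_periods(tl, policy):
            assert b - a >= 7200.0
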