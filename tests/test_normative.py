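"""Normative map construction: exclusion, preprocessing, metric, filters."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import signal as sig

from normkit.bands import BandScheme, DEFAULT_BANDS
from normkit.normative import (
    NormativeMap,
    PreprocessParams,
    WelchParams,
    aggregate_to_roi,
    apply_reference,
    band_log_rbp,
    band_rbp,
    build_normative_map,
    detect_noisy_channels,
    exclude_pathological,
    loo_outlier_filter,
    metric_config_hash,
    preprocess,
)
from normkit.spatial import build_channel_table
from normkit.temporal import SegmentRecord


def _segment(data, fs=256.0, names=None):
    data = np.asarray(data, dtype=float)
    return SegmentRecord(
        channel_names=names or [f"C{i}" for i in range(data.shape[0])],
        data=data,
        fs=fs,
        start_datetime="2024-01-01T10:00:00",
        duration=data.shape[1] / fs,
        wake_status="W",
        subject_id="SYNH_001",
        hospital="SYNH",
        segment_number=1,
    )


class TestExcludePathological:
    def test_printed_fixture(self, table1_coords, table2_flags, hippocampus_parc):
        table = build_channel_table(table1_coords, hippocampus_parc, flags=table2_flags)
        retained = exclude_pathological(table)
        assert retained == [f"LHIPP{i}" for i in range(6, 11)]

    def test_all_false_identity(self, table1_coords, hippocampus_parc):
        table = build_channel_table(table1_coords, hippocampus_parc)
        assert exclude_pathological(table) == table["name"].tolist()

    def test_unlocalised_dropped(self, hippocampus_parc):
        coords = pd.DataFrame(
            [
                ("A1", -30.0, -15.0, -9.0, "depth", "left"),
                ("FAR", -30.0, -15.0, 40.0, "depth", "left"),
            ],
            columns=["name", "x", "y", "z", "electrode_type", "hemisphere"],
        )
        table = build_channel_table(coords, hippocampus_parc)
        assert exclude_pathological(table) == ["A1"]


class TestDetectNoisy:
    def _homogeneous(self, n=11, seed=0):
        return np.random.default_rng(seed).normal(size=(n, 5000))

    def test_single_outlier(self):
        data = self._homogeneous()
        data[4] *= 10.0
        assert detect_noisy_channels(data) == ["4"]

    def test_homogeneous_none(self):
        assert detect_noisy_channels(self._homogeneous()) == []

    def test_symmetric_outliers(self):
        data = self._homogeneous()
        data[2] *= 10.0
        data[8] /= 10.0
        assert detect_noisy_channels(data) == ["2", "8"]

    def test_too_few_channels(self):
        with pytest.raises(ValueError, match="at least 3"):
            detect_noisy_channels(self._homogeneous(n=2))

    def test_named_channels(self):
        data = self._homogeneous(n=5)
        data[0] *= 20.0
        seg = _segment(data)
        assert detect_noisy_channels(seg) == ["C0"]


class TestPreprocess:
    def test_car_arithmetic(self):
        data = np.vstack([np.ones(100), 2 * np.ones(100)])
        out = apply_reference(data)
        np.testing.assert_allclose(out[0], -0.5)
        np.testing.assert_allclose(out[1], 0.5)

    def test_car_zero_mean(self):
        rng = np.random.default_rng(0)
        seg = _segment(rng.normal(size=(6, 4096)))
        out = preprocess(seg, PreprocessParams(target_fs=256.0))
        # CAR is applied before filtering; linear zero-phase filters keep
        # the cross-channel mean at zero
        np.testing.assert_allclose(out.data.mean(axis=0), 0.0, atol=1e-9)

    def test_notch_attenuation(self):
        fs = 512.0
        t = np.arange(int(30 * fs)) / fs
        x = np.sin(2 * np.pi * 50 * t) + np.sin(2 * np.pi * 10 * t)
        seg = _segment(np.vstack([x, x, x]), fs=fs)
        params = PreprocessParams(
            reference="none", bandpass=(0.5, 90.0), notch_base=50.0, target_fs=200.0
        )
        out = preprocess(seg, params)

        def power_at(data, fs_, freq):
            f, p = sig.welch(data, fs=fs_, nperseg=int(4 * fs_))
            return p[np.argmin(np.abs(f - freq))]

        before_50 = power_at(seg.data[0], fs, 50.0)
        after_50 = power_at(out.data[0], out.fs, 50.0)
        before_10 = power_at(seg.data[0], fs, 10.0)
        after_10 = power_at(out.data[0], out.fs, 10.0)
        assert 10 * np.log10(before_50 / after_50) >= 20.0
        assert abs(10 * np.log10(before_10 / after_10)) <= 1.0

    def test_resample_preserves_duration(self):
        seg = _segment(np.random.default_rng(1).normal(size=(3, 256 * 10)), fs=256.0)
        out = preprocess(seg, PreprocessParams(target_fs=200.0))
        assert out.fs == 200.0
        assert abs(out.data.shape[1] - 2000) <= 1

    def test_upsampling_rejected(self):
        seg = _segment(np.zeros((3, 1000)), fs=128.0)
        with pytest.raises(ValueError, match="upsampling"):
            preprocess(seg, PreprocessParams(target_fs=200.0))

    def test_bandpass_above_nyquist_rejected(self):
        seg = _segment(np.zeros((3, 1000)), fs=128.0)
        params = PreprocessParams(bandpass=(0.5, 90.0), target_fs=200.0)
        with pytest.raises(ValueError):
            preprocess(seg, PreprocessParams(bandpass=(0.5, 70.0), target_fs=128.0))


class TestBandRbp:
    def test_pure_alpha_tone(self):
        fs = 200.0
        t = np.arange(int(70 * fs)) / fs
        seg = _segment(np.vstack([np.sin(2 * np.pi * 10 * t)]), fs=fs)
        rbp = band_rbp(seg)
        assert rbp.loc["C0", "alpha"] > 0.9
        log = band_log_rbp(seg)
        assert log.loc["C0", "alpha"] > -0.046

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        seg = _segment(rng.normal(size=(5, 200 * 70)), fs=200.0)
        rbp = band_rbp(seg)
        np.testing.assert_allclose(rbp.sum(axis=1), 1.0, atol=1e-12)

    def test_white_noise_matches_bandwidth(self):
        total_bw = 47.5 - 1.0
        expected = {b: DEFAULT_BANDS.bandwidth(b) / total_bw for b in DEFAULT_BANDS.names}
        values = {b: [] for b in DEFAULT_BANDS.names}
        for seed in range(10):
            seg = _segment(
                np.random.default_rng(seed).normal(size=(1, 200 * 70)), fs=200.0
            )
            rbp = band_rbp(seg)
            for b in DEFAULT_BANDS.names:
                values[b].append(rbp.loc["C0", b])
        for b in DEFAULT_BANDS.names:
            arr = np.array(values[b])
            sem = arr.std(ddof=1) / np.sqrt(len(arr))
            assert abs(arr.mean() - expected[b]) < 3 * max(sem, 1e-4)

    def test_flat_channel_nan_not_inf(self):
        data = np.vstack([np.zeros(200 * 70), np.random.default_rng(0).normal(size=200 * 70)])
        log = band_log_rbp(_segment(data, fs=200.0))
        assert log.loc["C0"].isna().all()
        assert np.isfinite(log.loc["C1"]).all()

    def test_too_short_rejected(self):
        seg = _segment(np.zeros((2, 300)), fs=200.0)
        with pytest.raises(ValueError, match="two Welch windows"):
            band_rbp(seg)


class TestAggregate:
    def test_single_channel_passthrough(self):
        rbp = pd.DataFrame({"alpha": [0.4], "beta": [0.6]}, index=["C0"])
        out = aggregate_to_roi(rbp, {"C0": 17})
        assert out.loc[17, "alpha"] == pytest.approx(np.log10(0.4))

    def test_mean_then_log(self):
        rbp = pd.DataFrame({"alpha": [0.2, 0.4]}, index=["C0", "C1"])
        out = aggregate_to_roi(rbp, {"C0": 17, "C1": 17})
        assert out.loc[17, "alpha"] == pytest.approx(-0.5229, abs=1e-4)

    def test_matches_brute_force_groupby(self, rng):
        names = [f"C{i}" for i in range(12)]
        rbp = pd.DataFrame(
            rng.uniform(0.01, 1.0, size=(12, 3)), index=names, columns=["a", "b", "c"]
        )
        mapping = {n: int(rng.choice([17, 18, 53])) for n in names}
        out = aggregate_to_roi(rbp, mapping)
        for roi in set(mapping.values()):
            members = [n for n in names if mapping[n] == roi]
            for band in ("a", "b", "c"):
                want = np.log10(np.mean([rbp.loc[n, band] for n in members]))
                assert out.loc[roi, band] == pytest.approx(want)

    def test_unmapped_channel_rejected(self):
        rbp = pd.DataFrame({"a": [0.5]}, index=["C0"])
        with pytest.raises(ValueError, match="without an ROI"):
            aggregate_to_roi(rbp, {})


def _rows(values, roi=17, band="delta"):
    return pd.DataFrame(
        {
            "subject_id": [f"S{i:03d}" for i in range(len(values))],
            "roi_id": roi,
            "band": band,
            "value": values,
        }
    )


class TestLooFilter:
    def test_single_extreme_removed(self):
        # seed chosen so the clean draws contain no borderline LOO outlier
        rng = np.random.default_rng(2)
        values = list(rng.normal(0, 1, 30)) + [10.0]
        kept, removed = loo_outlier_filter(_rows(values))
        assert list(removed["subject_id"]) == ["S030"]
        assert len(kept) == 30

    def test_degenerate_spread_no_flags(self):
        kept, removed = loo_outlier_filter(_rows([1.0] * 10))
        assert removed.empty
        assert len(kept) == 10

    def test_deviating_value_in_degenerate_group_removed(self):
        kept, removed = loo_outlier_filter(_rows([0.0] * 30 + [10.0]))
        assert list(removed["subject_id"]) == ["S030"]

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        values = list(rng.normal(0, 1, 40)) + [8.0, -9.0]
        kept, _ = loo_outlier_filter(_rows(values))
        again, removed = loo_outlier_filter(kept)
        assert removed.empty
        pd.testing.assert_frame_equal(again, kept)

    def test_whole_subject_roi_removed_across_bands(self):
        rng = np.random.default_rng(2)
        frames = []
        for band in ("delta", "theta"):
            vals = list(rng.normal(0, 1, 30)) + ([15.0] if band == "delta" else [0.0])
            frames.append(_rows(vals, band=band))
        rows = pd.concat(frames, ignore_index=True)
        kept, removed = loo_outlier_filter(rows)
        # the planted subject's theta row goes too (same subject, same roi)
        assert sorted(removed["band"]) == ["delta", "theta"]

    def test_small_groups_untouched(self):
        kept, removed = loo_outlier_filter(_rows([0.0, 100.0]))
        assert removed.empty


class TestBuildMap:
    def test_min_n_threshold(self):
        rows = pd.concat(
            [_rows(list(np.zeros(28)) + [0.1], roi=17),
             _rows(list(np.zeros(31)) + [0.1] * 2, roi=18)],
            ignore_index=True,
        )
        nmap = build_normative_map(rows, min_n=30)
        assert nmap.roi_ids == [18]

    def test_empty_map_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            build_normative_map(_rows([0.0, 1.0]), min_n=30)

    def test_one_segment_per_subject(self):
        rows = pd.concat([_rows(np.zeros(10)), _rows(np.ones(10))], ignore_index=True)
        rows["segment_number"] = [1] * 10 + [2] * 10
        nmap = build_normative_map(rows, min_n=5)
        mean, sd, n = nmap.cell(17, "delta")
        assert (mean, n) == (0.0, 10)

    def test_mean_sd_n(self):
        values = [1.0, 2.0, 3.0, 4.0]
        nmap = build_normative_map(_rows(values), min_n=3)
        mean, sd, n = nmap.cell(17, "delta")
        assert mean == pytest.approx(2.5)
        assert sd == pytest.approx(np.std(values, ddof=1))
        assert n == 4

    def test_save_load_round_trip(self, tmp_path):
        nmap = build_normative_map(_rows(list(range(10))), min_n=5, config_hash="abc")
        nmap.save(tmp_path / "map.csv")
        back = NormativeMap.load(tmp_path / "map.csv")
        pd.testing.assert_frame_equal(back.table, nmap.table, check_dtype=False)
        assert back.config_hash == "abc"
        assert back.bands.to_dict() == nmap.bands.to_dict()

    def test_hash_changes_iff_config_changes(self):
        a = metric_config_hash(PreprocessParams())
        b = metric_config_hash(PreprocessParams())
        c = metric_config_hash(PreprocessParams(notch_base=60.0))
        assert a == b
        assert a != c
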