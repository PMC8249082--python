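"""Recording I/O, validation, filtering/decimation, and windowing."""

import numpy as np
import pytest

import physioconn as pc
from physioconn.recording import RecordingError, count_windows

ORGAN_MAP_6CH = {
    "EEG1": "BRAIN", "EEG2": "BRAIN", "EEG3": "BRAIN", "EEG4": "BRAIN",
    "ECG": "HEART", "PLETH": "LUNGS",
}


class TestTextDialect:
    def test_round_trip_is_bit_exact(self, tmp_path):
        rng = np.random.default_rng(0)
        rec = pc.MultichannelRecording(
            rng.standard_normal((50, 2)), 500.0, ["ECG", "PLETH"],
            {"ECG": "HEART", "PLETH": "LUNGS"},
        )
        path = tmp_path / "rec.tsv"
        pc.write_recording(rec, path)
        back = pc.read_recording(path, rec.organ_map)
        assert back.channel_labels == rec.channel_labels
        assert back.fs == rec.fs
        np.testing.assert_array_equal(back.data, rec.data)

    def test_single_channel_identity(self, tmp_path):
        path = tmp_path / "z.csv"
        path.write_text("# fs=500\nECG\n" + "0.0\n" * 10)
        rec = pc.read_recording(path, {"ECG": "HEART"})
        assert rec.data.shape == (10, 1)
        assert np.all(rec.data == 0)

    def test_nan_rejected_naming_channel_and_index(self, tmp_path):
        rows = ["# fs=500", "EEG1\tECG"] + ["0.1\t0.2"] * 10
        rows[2 + 5] = "0.1\tnan"
        path = tmp_path / "bad.tsv"
        path.write_text("\n".join(rows) + "\n")
        with pytest.raises(RecordingError, match=r"'ECG'.*index 5"):
            pc.read_recording(path, {"EEG1": "BRAIN", "ECG": "HEART"})

    def test_missing_channel_in_organ_map_rejected(self, tmp_path):
        path = tmp_path / "r.tsv"
        path.write_text("# fs=500\nEEG1\n0.0\n")
        with pytest.raises(RecordingError, match="PLETH"):
            pc.read_recording(path, {"EEG1": "BRAIN", "PLETH": "LUNGS"})

    def test_missing_sampling_rate_rejected(self, tmp_path):
        path = tmp_path / "r.tsv"
        path.write_text("EEG1\n0.0\n")
        with pytest.raises(RecordingError, match="sampling rate"):
            pc.read_recording(path, {"EEG1": "BRAIN"})


class TestEDF:
    def test_six_channel_edf_organ_counts(self, edf_writer):
        rng = np.random.default_rng(1)
        signals = [(lab, 500.0, rng.standard_normal(1000)) for lab in ORGAN_MAP_6CH]
        path = edf_writer(signals, record_duration=1.0)
        rec = pc.read_recording(path, ORGAN_MAP_6CH)
        assert rec.n_channels == 6
        assert rec.channel_labels == list(ORGAN_MAP_6CH)
        assert rec.organ_counts() == {"BRAIN": 4, "HEART": 1, "LUNGS": 1}
        assert rec.is_uniform and rec.fs == 500.0

    def test_edf_values_survive_quantization(self, edf_writer):
        rng = np.random.default_rng(2)
        data = rng.standard_normal(500)
        path = edf_writer([("EEG1", 500.0, data)])
        rec = pc.read_recording(path, {"EEG1": "BRAIN"})
        # EDF stores int16 and the reader may convert physical units by a
        # global factor; expect agreement to quantization resolution after
        # removing that factor (GPDC is scale invariant anyway).
        got = rec.channel_data("EEG1")
        scale = np.dot(got, data) / np.dot(data, data)
        assert scale > 0
        span = data.max() - data.min()
        assert np.max(np.abs(got / scale - data)) < span / 65535 * 2

    def test_mixed_rate_edf_loads_ragged_then_harmonizes(self, edf_writer):
        rng = np.random.default_rng(3)
        signals = [
            ("EEG1", 500.0, rng.standard_normal(1000)),
            ("ECG", 2000.0, rng.standard_normal(4000)),
        ]
        path = edf_writer(signals)
        rec = pc.read_recording(path, {"EEG1": "BRAIN", "ECG": "HEART"})
        assert not rec.is_uniform
        assert rec.channel_fs("ECG") == 2000.0
        uni = pc.lowpass_downsample(rec, cutoff_hz=200, order=4, target_fs=500)
        assert uni.is_uniform and uni.fs == 500.0
        assert uni.data.shape == (1000, 2)  # ECG length divided by 4


class TestLowpassDownsample:
    def test_decimation_by_four(self):
        rng = np.random.default_rng(4)
        rec = pc.MultichannelRecording(
            [rng.standard_normal(8000)], np.array([2000.0]), ["ECG"], {"ECG": "HEART"}
        )
        out = pc.lowpass_downsample(rec, 200, 4, 500)
        assert out.fs == 500.0 and out.n_samples == 2000

    def test_dc_channel_preserved(self):
        rec = pc.MultichannelRecording(
            [np.full(4000, 3.7)], np.array([2000.0]), ["ECG"], {"ECG": "HEART"}
        )
        out = pc.lowpass_downsample(rec, 200, 4, 500)
        # unity gain at 0 Hz: steady state equals the constant
        assert abs(out.data[-1, 0] - 3.7) < 1e-9
        assert abs(out.data[500:, 0].mean() - 3.7) < 1e-9

    def test_stopband_attenuation_matches_digital_butterworth(self):
        # 300 Hz sine through the 4th-order 200 Hz digital (bilinear) filter:
        # |H| = 1/sqrt(1 + (tan(w/2)/tan(wc/2))^8)
        fs = 2000.0
        t = np.arange(0, 8, 1 / fs)
        rec = pc.MultichannelRecording(
            [np.sin(2 * np.pi * 300 * t)], np.array([fs]), ["ECG"], {"ECG": "HEART"}
        )
        out = pc.lowpass_downsample(rec, 200, 4, 500)
        tail = out.data[out.n_samples // 2 :, 0]
        amp = np.sqrt(2) * tail.std()
        ratio = np.tan(np.pi * 300 / fs) / np.tan(np.pi * 200 / fs)
        expected = 1.0 / np.sqrt(1.0 + ratio**8)
        assert amp == pytest.approx(expected, rel=0.01)

    def test_non_integer_ratio_rejected(self):
        rec = pc.MultichannelRecording(
            [np.zeros(300) + 1.0], np.array([750.0]), ["ECG"], {"ECG": "HEART"}
        )
        with pytest.raises(RecordingError, match="divide"):
            pc.lowpass_downsample(rec, 200, 4, 500)

    def test_cutoff_above_target_nyquist_rejected(self):
        rec = pc.MultichannelRecording(
            np.zeros((100, 1)) + 1.0, 2000.0, ["ECG"], {"ECG": "HEART"}
        )
        with pytest.raises(RecordingError, match="Nyquist"):
            pc.lowpass_downsample(rec, 300, 4, 500)


class TestSegmentWindows:
    def test_window_geometry_and_counts(self):
        rng = np.random.default_rng(5)
        rec = pc.MultichannelRecording(
            rng.standard_normal((int(25 * 500), 6)), 500.0,
            list(ORGAN_MAP_6CH), ORGAN_MAP_6CH,
        )
        wins = list(pc.segment_windows(rec, pc.WindowSpec(10.0)))
        assert len(wins) == 2  # 25 s -> two 10 s windows, 5 s remainder dropped
        for k, (idx, start, block) in enumerate(wins):
            assert idx == k
            assert start == pytest.approx(10.0 * k)
            assert block.shape == (5000, 6)
            assert block.size == 30000
        # the windows tile a prefix of the recording exactly
        np.testing.assert_array_equal(
            np.concatenate([w[2] for w in wins]), rec.data[:10000]
        )

    def test_four_hours_gives_1440_windows(self):
        assert count_windows(4 * 3600 * 500, 500.0, pc.WindowSpec(10.0)) == 1440

    def test_too_short_recording_rejected(self):
        rec = pc.MultichannelRecording(
            np.ones((100, 1)), 500.0, ["ECG"], {"ECG": "HEART"}
        )
        with pytest.raises(RecordingError, match="shorter"):
            list(pc.segment_windows(rec, pc.WindowSpec(10.0)))

    def test_overlap_steps(self):
        rec = pc.MultichannelRecording(
            np.arange(40, dtype=float)[:, None], 2.0, ["ECG"], {"ECG": "HEART"}
        )
        wins = list(pc.segment_windows(rec, pc.WindowSpec(10.0, 5.0)))
        starts = [w[1] for w in wins]
        assert starts == [0.0, 5.0, 10.0]
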