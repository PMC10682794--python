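"""Dataset construction: generation, segmentation, framing, splitting."""

import numpy as np
import pytest

from neurotune import (
    DEFAULT_CLASS_SPECS,
    LABELS,
    MultichannelRecording,
    SegmentedDataset,
    SyntheticClassSpec,
    frame_with_lags,
    make_synthetic_dataset,
    normalize,
    read_bonn_directory,
    recombine_segments,
    segment_recording,
    split_dataset,
    synthesize_recording,
)


def rng(seed=0):
    return np.random.default_rng(seed)


class TestSynthesize:
    def test_degenerate_spec_pure_sinusoid(self):
        spec = SyntheticClassSpec((10.0, 10.0), 1.0, 0.0, 0.0, 0.0)
        rec = synthesize_recording(spec, 2000, 2, rng())
        assert np.abs(rec.samples).max() == pytest.approx(1.0, abs=1e-3)
        # spectral check: dominant frequency of channel 0 is 10 Hz
        from neurotune.eeg import SAMPLING_RATE

        x = rec.samples[:, 0]
        freqs = np.fft.rfftfreq(x.size, d=1 / SAMPLING_RATE)
        peak = freqs[np.abs(np.fft.rfft(x)).argmax()]
        assert peak == pytest.approx(10.0, abs=0.2)

    def test_variance_of_sinusoid_plus_noise(self):
        spec = SyntheticClassSpec((9.0, 11.0), 1.0, 0.0, 0.0, 0.5)
        rec = synthesize_recording(spec, 10000, 4, rng(1))
        expected = 1.0**2 / 2 + 0.5**2
        for c in range(4):
            assert rec.samples[:, c].var() == pytest.approx(expected, rel=0.10)

    def test_determinism(self):
        spec = DEFAULT_CLASS_SPECS["anomalous"]
        a = synthesize_recording(spec, 500, 3, rng(9), class_label="anomalous")
        b = synthesize_recording(spec, 500, 3, rng(9), class_label="anomalous")
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_spikes_add_energy(self):
        base = SyntheticClassSpec((8.0, 13.0), 1.0, 0.0, 0.0, 0.0)
        spiky = SyntheticClassSpec((8.0, 13.0), 1.0, 50.0, 4.0, 0.0)
        a = synthesize_recording(base, 4000, 1, rng(2))
        b = synthesize_recording(spiky, 4000, 1, rng(2))
        assert b.samples.var() > a.samples.var()


class TestSegmentation:
    def test_bonn_arithmetic(self):
        rec = MultichannelRecording(np.zeros((4096, 3)), "normal")
        ds = segment_recording(rec, 158)
        assert len(ds) == 25  # floor(4096 / 158), 146 rows dropped
        assert ds.windows.shape == (25, 158, 3)

    def test_exact_single_window(self):
        rec = MultichannelRecording(np.zeros((158, 2)), "seizure")
        ds = segment_recording(rec, 158)
        assert len(ds) == 1 and ds.labels[0] == LABELS["seizure"]

    def test_too_short_errors(self):
        rec = MultichannelRecording(np.zeros((157, 1)), "normal")
        with pytest.raises(ValueError):
            segment_recording(rec, 158)


class TestRecombination:
    def _two_parts(self):
        a = segment_recording(
            MultichannelRecording(np.ones((25 * 158, 2)), "normal"), 158
        )
        b = segment_recording(
            MultichannelRecording(-np.ones((25 * 158, 2)), "anomalous"), 158
        )
        return a, b

    def test_counts_conserved(self):
        a, b = self._two_parts()
        ds = recombine_segments([a, b], rng(4))
        assert len(ds) == 50
        assert (ds.labels == LABELS["normal"]).sum() == 25
        assert (ds.labels == LABELS["anomalous"]).sum() == 25
        # labels travel with windows: sign identifies the source
        signs = np.sign(ds.windows[:, 0, 0])
        np.testing.assert_array_equal(signs == 1, ds.labels == 0)

    def test_single_part_is_permutation(self):
        a, _ = self._two_parts()
        ds = recombine_segments([a], rng(5))
        assert len(ds) == 25
        np.testing.assert_array_equal(np.sort(ds.labels), np.sort(a.labels))

    def test_seeded_permutation_reproducible(self):
        a, b = self._two_parts()
        d1 = recombine_segments([a, b], rng(6))
        d2 = recombine_segments([a, b], rng(6))
        np.testing.assert_array_equal(d1.labels, d2.labels)

    def test_mismatched_parts_rejected(self):
        a, _ = self._two_parts()
        c = segment_recording(
            MultichannelRecording(np.zeros((100, 2)), "normal"), 50
        )
        with pytest.raises(ValueError):
            recombine_segments([a, c], rng(7))


class TestFraming:
    def test_single_window_count(self):
        ds = SegmentedDataset(np.zeros((1, 158, 2)), [0], 158)
        frame = frame_with_lags(ds, lags=15)
        assert len(frame) == 144  # 158 - 15 + 1
        assert (frame.labels == 0).all()

    def test_boundary_instances_dropped(self):
        windows = np.zeros((2, 158, 1))
        ds = SegmentedDataset(windows, [0, 1], 158)
        frame = frame_with_lags(ds, lags=15)
        assert len(frame) == 288  # 2*144 kept, 14 mixed-context dropped

    def test_same_label_boundary_kept(self):
        ds = SegmentedDataset(np.zeros((2, 158, 1)), [1, 1], 158)
        frame = frame_with_lags(ds, lags=15)
        assert len(frame) == 2 * 158 - 15 + 1

    def test_lags_one_keeps_everything(self):
        ds = SegmentedDataset(np.zeros((3, 50, 2)), [0, 1, 0], 50)
        frame = frame_with_lags(ds, lags=1)
        assert len(frame) == 150

    def test_label_of_last_row_mode(self):
        ds = SegmentedDataset(np.zeros((2, 50, 1)), [0, 1], 50)
        frame = frame_with_lags(ds, lags=10, boundary="last")
        assert len(frame) == 100 - 10 + 1
        assert (frame.labels == np.repeat([0, 1], [41, 50])).all()

    def test_lags_longer_than_series_errors(self):
        ds = SegmentedDataset(np.zeros((1, 10, 1)), [0], 10)
        with pytest.raises(ValueError):
            frame_with_lags(ds, lags=11)

    def test_instance_rows_are_the_lag_context(self):
        series = np.arange(40, dtype=float).reshape(40, 1)
        ds = SegmentedDataset(series.reshape(1, 40, 1), [0], 40)
        frame = frame_with_lags(ds, lags=5)
        np.testing.assert_allclose(frame.instances[0, :, 0], [0, 1, 2, 3, 4])
        np.testing.assert_allclose(frame.instances[-1, :, 0], [35, 36, 37, 38, 39])


class TestSplitNormalize:
    def _frame(self, n):
        ds = SegmentedDataset(
            np.random.default_rng(0).normal(size=(1, n + 14, 2)), [0], n + 14
        )
        return frame_with_lags(ds, lags=15)

    def test_exact_fractions(self):
        frame = split_dataset(self._frame(100))
        tags = frame.split_tag
        assert (tags == "train").sum() == 70
        assert (tags == "val").sum() == 10
        assert (tags == "test").sum() == 20

    def test_floor_rule_remainder_to_test(self):
        frame = split_dataset(self._frame(103))
        tags = frame.split_tag
        assert [(tags == t).sum() for t in ("train", "val", "test")] == [72, 10, 21]

    def test_empty_split_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(self._frame(100), fractions=(1.0, 0.0, 0.0))

    def test_minmax_affine_map(self):
        inst = np.linspace(-10, 10, 300).reshape(100, 3, 1)
        from neurotune import SupervisedFrame

        frame = split_dataset(SupervisedFrame(inst, np.tile([0, 1], 50), 3))
        scaled, record = normalize(frame)
        tr, _ = frame.subset("train")
        assert record.minimum[0] == tr.min() and record.maximum[0] == tr.max()
        assert scaled.instances.min() == pytest.approx(0.0)
        # test values above the train range exceed 1 (no clipping)
        assert scaled.instances.max() > 1.0
        # inversion round-trips
        np.testing.assert_allclose(
            record.invert(scaled.instances), frame.instances
        )

    def test_constant_channel_warns_and_zeroes(self):
        from neurotune import SupervisedFrame

        inst = np.ones((50, 4, 1))
        frame = split_dataset(SupervisedFrame(inst, np.tile([0, 1], 25), 4))
        with pytest.warns(UserWarning):
            scaled, _ = normalize(frame)
        assert (scaled.instances == 0).all()


class TestCsvRoundTrip:
    def test_segmented_dataset_round_trip(self, tmp_path):
        w = np.random.default_rng(3).normal(size=(6, 20, 2))
        ds = SegmentedDataset(w, [0, 1, 0, 1, 2, 2], 20)
        path = tmp_path / "ds.csv"
        ds.to_csv(path)
        back = SegmentedDataset.from_csv(path)
        np.testing.assert_allclose(back.windows, ds.windows)
        np.testing.assert_array_equal(back.labels, ds.labels)


class TestBonnReader:
    def _write(self, tmp_path, name, lines):
        (tmp_path / name).write_text("\n".join(str(v) for v in lines) + "\n")

    def test_shape_and_channel_order(self, tmp_path):
        for i, name in enumerate(["b.txt", "a.txt", "c.txt"]):
            self._write(tmp_path, name, [i] * 100)
        rec = read_bonn_directory(tmp_path, expected_length=100)
        assert rec.samples.shape == (100, 3)
        # channels sorted by filename: a.txt (value 1) first
        np.testing.assert_allclose(rec.samples[0], [1, 0, 2])

    def test_parse_error_cites_line(self, tmp_path):
        lines = ["1"] * 6 + ["12a"] + ["1"] * 3
        self._write(tmp_path, "bad.txt", lines)
        with pytest.raises(ValueError, match="line 7"):
            read_bonn_directory(tmp_path, expected_length=10)

    def test_truncate_dialect(self, tmp_path):
        self._write(tmp_path, "x.txt", list(range(101)))
        with pytest.raises(ValueError, match="101"):
            read_bonn_directory(tmp_path, expected_length=100)
        rec = read_bonn_directory(tmp_path, expected_length=100, truncate=True)
        assert rec.samples.shape == (100, 1)

    def test_short_file_errors(self, tmp_path):
        self._write(tmp_path, "x.txt", [1] * 90)
        with pytest.raises(ValueError):
            read_bonn_directory(tmp_path, expected_length=100)


class TestEndToEnd:
    def test_binary_and_multiclass_layouts_from_one_seed(self):
        b, _ = make_synthetic_dataset(
            n_classes=2, windows_per_class=4, channels=2,
            window_length=60, lags=5, seed=11,
        )
        m, _ = make_synthetic_dataset(
            n_classes=3, windows_per_class=4, channels=2,
            window_length=60, lags=5, seed=11,
        )
        assert set(np.unique(b.labels)) == {0, 1}
        assert set(np.unique(m.labels)) == {0, 1, 2}

    def test_window_level_bandpower_separability(self):
        """With default class recipes a variance threshold separates
        normal from anomalous windows at >90% accuracy."""
        rng_ = np.random.default_rng(42)
        parts = []
        for name in ("normal", "anomalous"):
            rec = synthesize_recording(
                DEFAULT_CLASS_SPECS[name], 25 * 158, 8, rng_, class_label=name
            )
            parts.append(segment_recording(rec, 158))
        ds = recombine_segments(parts, rng_)
        power = ds.windows.var(axis=(1, 2))
        # best threshold by 1-d sweep
        order = np.argsort(power)
        best = 0
        for thr in power:
            acc = np.mean((power > thr) == (ds.labels == 1))
            best = max(best, acc, 1 - acc)
        assert best > 0.90

    def test_label_conservation_through_pipeline(self):
        frame, _ = make_synthetic_dataset(
            n_classes=2, windows_per_class=6, channels=2,
            window_length=60, lags=5, seed=3,
        )
        # each kept instance carries the label of its source window
        counts = np.bincount(frame.labels)
        # 6 windows x (60-5+1) instances max per class, minus boundary drops
        assert counts.sum() == len(frame)
        assert (counts > 0).all()
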