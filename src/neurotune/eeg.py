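"""EEG dataset construction.

Covers both real and synthetic inputs:

* a reader for Bonn-style archives — directories of plain-text files, one
  integer amplitude sample per line, one file per electrode, nominally
  4,096 usable samples per file;
* a synthetic multichannel generator that emulates the statistical
  contrast between three EEG regimes: normal alpha-band background,
  interictal (spike-laden, theta-slowed) activity, and high-amplitude
  rhythmic seizure activity;
* the preprocessing chain: fixed-width segmentation (default 158-sample
  windows), seeded recombination of class windows into one continuous
  labeled recording, lag framing into supervised instances, a contiguous
  70/10/20 split, and train-fitted min-max normalization.

Class labels are 0 = normal, 1 = anomalous (interictal), 2 = seizure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "LABELS",
    "MultichannelRecording",
    "SegmentedDataset",
    "SupervisedFrame",
    "SyntheticClassSpec",
    "ScalingRecord",
    "DEFAULT_CLASS_SPECS",
    "save_class_specs",
    "load_class_specs",
    "read_bonn_directory",
    "synthesize_recording",
    "segment_recording",
    "recombine_segments",
    "frame_with_lags",
    "split_dataset",
    "normalize",
    "make_synthetic_dataset",
]

LABELS = {"normal": 0, "anomalous": 1, "seizure": 2}

#: nominal Bonn sampling rate (Hz); used only to convert band frequencies
#: into per-sample phase increments.
SAMPLING_RATE = 173.61


@dataclass
class MultichannelRecording:
    """time x channels amplitude matrix with a single class label."""

    samples: np.ndarray
    class_label: str
    source_tag: str = "synthetic"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] < 1:
            raise ValueError("samples must be a 2-d time x channels matrix")
        if np.isnan(self.samples).any():
            raise ValueError("recording contains missing values")
        if self.class_label not in LABELS:
            raise ValueError(f"unknown class label {self.class_label!r}")

    @property
    def channels(self) -> int:
        return self.samples.shape[1]

    def __len__(self) -> int:
        return self.samples.shape[0]


@dataclass
class SegmentedDataset:
    """Fixed-width windows with one label per window."""

    windows: np.ndarray  # (n_windows, window_length, channels)
    labels: np.ndarray  # (n_windows,)
    window_length: int
    permutation_seed: int | None = None

    def __post_init__(self) -> None:
        self.windows = np.asarray(self.windows, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.windows.ndim != 3:
            raise ValueError("windows must be (n, window_length, channels)")
        if self.windows.shape[1] != self.window_length:
            raise ValueError("window rows do not match window_length")
        if self.windows.shape[0] != self.labels.size:
            raise ValueError("one label per window required")

    @property
    def channels(self) -> int:
        return self.windows.shape[2]

    def __len__(self) -> int:
        return self.windows.shape[0]

    def to_csv(self, path: str | Path) -> None:
        """Long-format export: window_id, label, channel, row, value."""
        n, L, C = self.windows.shape
        wid, row, ch = np.meshgrid(
            np.arange(n), np.arange(L), np.arange(C), indexing="ij"
        )
        pd.DataFrame(
            {
                "window_id": wid.ravel(),
                "label": np.repeat(self.labels, L * C),
                "channel": ch.ravel(),
                "row": row.ravel(),
                "value": self.windows.ravel(),
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SegmentedDataset":
        df = pd.read_csv(path)
        n = int(df["window_id"].max()) + 1
        L = int(df["row"].max()) + 1
        C = int(df["channel"].max()) + 1
        windows = np.empty((n, L, C))
        windows[
            df["window_id"].to_numpy(),
            df["row"].to_numpy(),
            df["channel"].to_numpy(),
        ] = df["value"].to_numpy()
        labels = (
            df.drop_duplicates("window_id")
            .sort_values("window_id")["label"]
            .to_numpy()
        )
        return cls(windows=windows, labels=labels, window_length=L)


@dataclass
class SupervisedFrame:
    """Lag-framed supervised instances, optionally split-tagged."""

    instances: np.ndarray  # (n, lags, channels)
    labels: np.ndarray  # (n,)
    lags: int
    split_tag: np.ndarray | None = None  # per-instance {train,val,test}

    def __post_init__(self) -> None:
        self.instances = np.asarray(self.instances, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.instances.ndim != 3 or self.instances.shape[1] != self.lags:
            raise ValueError("instances must be (n, lags, channels)")
        if self.instances.shape[0] != self.labels.size:
            raise ValueError("one label per instance required")

    def __len__(self) -> int:
        return self.instances.shape[0]

    @property
    def channels(self) -> int:
        return self.instances.shape[2]

    @property
    def n_classes(self) -> int:
        return int(self.labels.max()) + 1

    def subset(self, tag: str) -> tuple[np.ndarray, np.ndarray]:
        if self.split_tag is None:
            raise ValueError("frame has not been split")
        mask = self.split_tag == tag
        return self.instances[mask], self.labels[mask]


@dataclass(frozen=True)
class SyntheticClassSpec:
    """Generator recipe for one EEG class.

    base_frequency_band
        (low, high) Hz of the sinusoidal background rhythm; one frequency
        is drawn per channel.
    base_amplitude
        peak amplitude of the background rhythm (arbitrary uV-like units).
    spike_rate
        expected transient events per 1,000 samples, per channel.
    spike_amplitude
        peak amplitude of the biphasic spike waveform.
    noise_sd
        standard deviation of additive white noise.
    """

    base_frequency_band: tuple[float, float]
    base_amplitude: float
    spike_rate: float = 0.0
    spike_amplitude: float = 0.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        lo, hi = self.base_frequency_band
        if lo > hi:
            raise ValueError("band low must be <= high")
        if min(self.base_amplitude, self.spike_rate, self.spike_amplitude, self.noise_sd) < 0:
            raise ValueError("rates and amplitudes must be >= 0")


# Default class recipes.  Normal mimics an alpha (8-13 Hz) background;
# interictal activity combines theta slowing with higher amplitude and
# sparse high-voltage biphasic spikes; seizure is a high-amplitude ~3 Hz
# rhythmic discharge.  These are generator conventions chosen to mirror
# the qualitative contrast between healthy, interictal and ictal EEG.
DEFAULT_CLASS_SPECS: dict[str, SyntheticClassSpec] = {
    "normal": SyntheticClassSpec((8.0, 13.0), 1.0, 0.0, 0.0, 0.3),
    "anomalous": SyntheticClassSpec((4.0, 8.0), 2.0, 5.0, 4.0, 0.3),
    "seizure": SyntheticClassSpec((3.0, 3.0), 3.0, 0.0, 0.0, 0.3),
}

#: biphasic spike template width in samples (~70 ms at the nominal rate).
_SPIKE_WIDTH = 12


def save_class_specs(specs: dict[str, SyntheticClassSpec], path) -> None:
    """Write generator recipes to YAML."""
    import yaml

    payload = {
        name: {
            "base_frequency_band": list(s.base_frequency_band),
            "base_amplitude": s.base_amplitude,
            "spike_rate": s.spike_rate,
            "spike_amplitude": s.spike_amplitude,
            "noise_sd": s.noise_sd,
        }
        for name, s in specs.items()
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh)


def load_class_specs(path) -> dict[str, SyntheticClassSpec]:
    import yaml

    with open(path) as fh:
        payload = yaml.safe_load(fh)
    return {
        name: SyntheticClassSpec(
            base_frequency_band=tuple(d["base_frequency_band"]),
            base_amplitude=d["base_amplitude"],
            spike_rate=d.get("spike_rate", 0.0),
            spike_amplitude=d.get("spike_amplitude", 0.0),
            noise_sd=d.get("noise_sd", 0.0),
        )
        for name, d in payload.items()
    }


def read_bonn_directory(
    path: str | Path,
    expected_length: int = 4096,
    class_label: str = "normal",
    truncate: bool = False,
) -> MultichannelRecording:
    """Read a directory of one-integer-per-line channel files.

    Files are ordered by sorted filename, one file per channel.  Files
    longer than ``expected_length`` raise unless ``truncate`` is set
    (some archive dialects carry one extra line); shorter files always
    raise.
    """
    path = Path(path)
    files = sorted(p for p in path.iterdir() if p.is_file())
    if not files:
        raise FileNotFoundError(f"no channel files in {path}")
    columns = []
    for f in files:
        values = []
        for lineno, line in enumerate(f.read_text().splitlines(), start=1):
            line = line.strip()
            if not line:
                continue
            try:
                values.append(float(line))
            except ValueError:
                raise ValueError(
                    f"{f.name}: non-numeric value {line!r} on line {lineno}"
                ) from None
        if len(values) > expected_length:
            if not truncate:
                raise ValueError(
                    f"{f.name}: {len(values)} samples, expected "
                    f"{expected_length} (pass truncate=True to trim)"
                )
            values = values[:expected_length]
        elif len(values) < expected_length:
            raise ValueError(
                f"{f.name}: {len(values)} samples, expected {expected_length}"
            )
        columns.append(values)
    return MultichannelRecording(
        samples=np.array(columns).T,
        class_label=class_label,
        source_tag=path.name,
    )


def _spike_template(amplitude: float) -> np.ndarray:
    """One full sine cycle: sharp positive deflection then undershoot."""
    k = np.arange(_SPIKE_WIDTH)
    return amplitude * np.sin(2.0 * np.pi * k / _SPIKE_WIDTH)


def synthesize_recording(
    spec: SyntheticClassSpec,
    length: int,
    channels: int,
    rng: np.random.Generator,
    class_label: str = "normal",
    sampling_rate: float = SAMPLING_RATE,
) -> MultichannelRecording:
    """Generate one multichannel recording from a class recipe.

    Each channel is an independent band-limited sinusoid (random
    frequency in the band, random phase) plus Poisson-placed biphasic
    spikes plus white noise.  Fully deterministic under a fixed rng.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    t = np.arange(length) / sampling_rate
    lo, hi = spec.base_frequency_band
    data = np.empty((length, channels))
    for c in range(channels):
        freq = rng.uniform(lo, hi) if hi > lo else lo
        phase = rng.uniform(0.0, 2.0 * np.pi)
        chan = spec.base_amplitude * np.sin(2.0 * np.pi * freq * t + phase)
        if spec.spike_rate > 0 and spec.spike_amplitude > 0:
            n_spikes = rng.poisson(spec.spike_rate * length / 1000.0)
            template = _spike_template(spec.spike_amplitude)
            for _ in range(n_spikes):
                start = int(rng.integers(0, max(1, length - _SPIKE_WIDTH)))
                stop = min(start + _SPIKE_WIDTH, length)
                chan[start:stop] += template[: stop - start]
        if spec.noise_sd > 0:
            chan = chan + rng.normal(0.0, spec.noise_sd, size=length)
        data[:, c] = chan
    return MultichannelRecording(samples=data, class_label=class_label)


def segment_recording(
    rec: MultichannelRecording, window_length: int = 158
) -> SegmentedDataset:
    """Cut into floor(length/window_length) consecutive windows.

    Trailing samples that do not fill a window are dropped; every window
    inherits the recording's class label.
    """
    n = len(rec) // window_length
    if n < 1:
        raise ValueError(
            f"recording of {len(rec)} rows shorter than one "
            f"{window_length}-row window"
        )
    usable = rec.samples[: n * window_length]
    windows = usable.reshape(n, window_length, rec.channels)
    labels = np.full(n, LABELS[rec.class_label])
    return SegmentedDataset(windows=windows, labels=labels, window_length=window_length)


def recombine_segments(
    parts: list[SegmentedDataset], rng: np.random.Generator
) -> SegmentedDataset:
    """Pool windows from all parts and shuffle by a seeded permutation.

    The permuted order defines one continuous labeled recording; labels
    travel with their windows.
    """
    if not parts:
        raise ValueError("need at least one part")
    L = parts[0].window_length
    C = parts[0].channels
    for p in parts:
        if p.window_length != L or p.channels != C:
            raise ValueError("all parts must share window_length and channels")
    windows = np.concatenate([p.windows for p in parts])
    labels = np.concatenate([p.labels for p in parts])
    perm = rng.permutation(len(labels))
    return SegmentedDataset(
        windows=windows[perm], labels=labels[perm], window_length=L
    )


def frame_with_lags(
    ds: SegmentedDataset, lags: int = 15, boundary: str = "drop"
) -> SupervisedFrame:
    """Frame the continuous recording into supervised lag instances.

    Windows are concatenated in order into one continuous series; the
    instance at row i consists of rows [i-lags+1 .. i] and carries the
    label of the window containing row i.  With ``boundary='drop'``
    (default) instances whose lag context spans windows with different
    labels are removed — they would otherwise carry systematically
    mislabeled context.  ``boundary='last'`` keeps them, labeled by
    their final row.
    """
    if lags < 1:
        raise ValueError("lags must be >= 1")
    if boundary not in ("drop", "last"):
        raise ValueError("boundary must be 'drop' or 'last'")
    n, L, C = ds.windows.shape
    series = ds.windows.reshape(n * L, C)
    row_labels = np.repeat(ds.labels, L)
    total = series.shape[0]
    if total < lags:
        raise ValueError("lags longer than the total series")
    sw = np.lib.stride_tricks.sliding_window_view
    instances = sw(series, lags, axis=0).transpose(0, 2, 1)  # (m, lags, C)
    label_ctx = sw(row_labels, lags)  # (m, lags)
    labels = label_ctx[:, -1]
    if boundary == "drop" and lags > 1:
        keep = (label_ctx == labels[:, None]).all(axis=1)
        instances, labels = instances[keep], labels[keep]
    return SupervisedFrame(
        instances=np.ascontiguousarray(instances),
        labels=labels.copy(),
        lags=lags,
    )


def split_dataset(
    frame: SupervisedFrame,
    fractions: tuple[float, float, float] = (0.70, 0.10, 0.20),
) -> SupervisedFrame:
    """Tag a contiguous 70/10/20 train/val/test split, in instance order.

    Counts are floor-based with the remainder assigned to test.
    """
    if not np.isclose(sum(fractions), 1.0):
        raise ValueError("fractions must sum to 1")
    n = len(frame)
    n_train = int(n * fractions[0])
    n_val = int(n * fractions[1])
    n_test = n - n_train - n_val
    if min(n_train, n_val, n_test) < 1:
        raise ValueError(
            f"split {fractions} leaves an empty subset at n={n}"
        )
    tags = np.empty(n, dtype=object)
    tags[:n_train] = "train"
    tags[n_train : n_train + n_val] = "val"
    tags[n_train + n_val :] = "test"
    return SupervisedFrame(
        instances=frame.instances,
        labels=frame.labels,
        lags=frame.lags,
        split_tag=tags,
    )


@dataclass
class ScalingRecord:
    """Per-channel train-split min/max, kept for inversion."""

    minimum: np.ndarray
    maximum: np.ndarray

    def apply(self, x: np.ndarray) -> np.ndarray:
        span = self.maximum - self.minimum
        safe = np.where(span > 0, span, 1.0)
        out = (x - self.minimum) / safe
        return np.where(span > 0, out, 0.0)

    def invert(self, x: np.ndarray) -> np.ndarray:
        return x * (self.maximum - self.minimum) + self.minimum


def normalize(frame: SupervisedFrame) -> tuple[SupervisedFrame, ScalingRecord]:
    """Per-channel min-max scaling fitted on the training split only.

    Applied to every split without clipping, so test values outside the
    training range map outside [0, 1].  A constant training channel is
    mapped to all zeros with a warning.
    """
    if frame.split_tag is None:
        raise ValueError("split the frame before normalizing")
    train_x, _ = frame.subset("train")
    minimum = train_x.min(axis=(0, 1))
    maximum = train_x.max(axis=(0, 1))
    if np.any(maximum == minimum):
        warnings.warn(
            "constant channel on the training split; scaled to 0",
            stacklevel=2,
        )
    record = ScalingRecord(minimum=minimum, maximum=maximum)
    return (
        SupervisedFrame(
            instances=record.apply(frame.instances),
            labels=frame.labels,
            lags=frame.lags,
            split_tag=frame.split_tag,
        ),
        record,
    )


def make_synthetic_dataset(
    n_classes: int = 2,
    windows_per_class: int = 25,
    channels: int = 8,
    window_length: int = 158,
    lags: int = 15,
    seed: int = 42,
    class_specs: dict[str, SyntheticClassSpec] | None = None,
) -> tuple[SupervisedFrame, ScalingRecord]:
    """End-to-end synthetic dataset: generate, segment, recombine,
    frame, split, normalize.

    ``n_classes=2`` builds the binary normal/anomalous layout,
    ``n_classes=3`` adds the seizure class.  One seed drives every
    random choice, so both layouts are reproducible from it.
    """
    if n_classes not in (2, 3):
        raise ValueError("n_classes must be 2 or 3")
    specs = class_specs or DEFAULT_CLASS_SPECS
    names = ["normal", "anomalous", "seizure"][:n_classes]
    rng = np.random.default_rng(seed)
    parts = []
    for name in names:
        rec = synthesize_recording(
            specs[name],
            length=windows_per_class * window_length,
            channels=channels,
            rng=rng,
            class_label=name,
        )
        parts.append(segment_recording(rec, window_length))
    combined = recombine_segments(parts, rng)
    frame = frame_with_lags(combined, lags=lags)
    return normalize(split_dataset(frame))
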