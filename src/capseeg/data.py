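"""Segment containers, CSV I/O, restructuring, and synthetic EEG generation.

The pipeline's universal currency is the :class:`SegmentSet`: a matrix of
fixed-length single-channel EEG segments (rows) with one integer label per
row.  The canonical public corpus this emulates stores one-second segments of
178 samples cut from 23.5-second recordings of 4097 samples, labelled with
five recording conditions:

``1`` (a)  ictal activity (epileptic seizure),
``2`` (b)  interictal, electrode in the tumour region,
``3`` (c)  interictal, healthy region of a tumour patient,
``4`` (d)  healthy volunteer, eyes closed,
``5`` (e)  healthy volunteer, eyes open.

In the binary relabelling, class 1 (seizure) maps to label 1 and classes
2-5 collapse to label 0.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

FIVE_CLASS_NAMES = ("a", "b", "c", "d", "e")
BINARY_CLASS_NAMES = ("non_seizure", "seizure")

DEFAULT_SEGMENT_LEN = 178
DEFAULT_RECORDING_LEN = 4097
DEFAULT_SAMPLING_RATE = 178.0


@dataclass
class SegmentSet:
    """Fixed-length signal segments with integer labels.

    Parameters
    ----------
    signals
        Array ``[n_segments, segment_len]`` of amplitudes (µV-scale,
        unitless internally).
    labels
        Integer labels, one per segment.  ``{1..5}`` under the five-class
        scheme, ``{0, 1}`` under the binary scheme.
    label_scheme
        ``"five_class"`` or ``"binary"``.
    class_names
        Ordered class names.
    sampling_rate
        Samples per second (178 by convention, so one segment is one second).
    """

    signals: np.ndarray
    labels: np.ndarray
    label_scheme: str = "five_class"
    class_names: tuple = FIVE_CLASS_NAMES
    sampling_rate: float = DEFAULT_SAMPLING_RATE

    def __post_init__(self):
        self.signals = np.asarray(self.signals, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.signals.ndim != 2:
            raise ValueError(
                f"signals must be 2-D [n_segments, segment_len], got shape "
                f"{self.signals.shape}"
            )
        if self.signals.shape[0] != self.labels.shape[0]:
            raise ValueError(
                f"{self.signals.shape[0]} segments but "
                f"{self.labels.shape[0]} labels"
            )
        if self.label_scheme not in ("five_class", "binary"):
            raise ValueError(f"unknown label scheme {self.label_scheme!r}")
        if self.n_segments:
            valid = {1, 2, 3, 4, 5} if self.label_scheme == "five_class" else {0, 1}
            bad = set(np.unique(self.labels)) - valid
            if bad:
                raise ValueError(
                    f"labels {sorted(bad)} invalid for scheme {self.label_scheme}"
                )

    @property
    def n_segments(self) -> int:
        return self.signals.shape[0]

    @property
    def segment_len(self) -> int:
        return self.signals.shape[1]

    def class_counts(self) -> dict:
        vals, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))

    def subset(self, idx) -> "SegmentSet":
        return dataclasses.replace(
            self, signals=self.signals[idx], labels=self.labels[idx]
        )


@dataclass
class RecordingSet:
    """Raw per-recording vectors (nominally 4097 samples ≈ 23.5 s)."""

    recordings: np.ndarray
    labels: np.ndarray
    duration_s: float = 23.5

    def __post_init__(self):
        self.recordings = np.asarray(self.recordings, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.recordings.ndim != 2:
            raise ValueError("recordings must be 2-D [n_recordings, length]")
        if self.recordings.shape[0] != self.labels.shape[0]:
            raise ValueError("recording/label count mismatch")

    @property
    def n_recordings(self) -> int:
        return self.recordings.shape[0]

    @property
    def recording_len(self) -> int:
        return self.recordings.shape[1]


@dataclass
class ClassSynthParams:
    """Generator knobs for one synthetic class.

    amplitude: scale of the deterministic waveform component (µV-scale).
    osc_freq_hz: frequency of the oscillatory component; 0 disables it.
    spike_rate: expected transient spikes per second (Poisson).
    spike_amp: multiplier on `amplitude` for transient spikes.
    ar_coeffs: AR(2) coefficients of the coloured background process.
    noise_sd: standard deviation of the white innovation / sensor noise.
    spike_wave: if True the oscillation is a sharp spike-and-wave shape
        (rectified-peak waveform) rather than a sinusoid.
    """

    amplitude: float = 0.0
    osc_freq_hz: float = 0.0
    spike_rate: float = 0.0
    spike_amp: float = 3.0
    ar_coeffs: tuple = (1.2, -0.4)
    noise_sd: float = 10.0
    spike_wave: bool = False


def default_class_params() -> dict:
    """Per-class defaults emulating the corpus's qualitative structure.

    Class a: ~3 Hz spike-and-wave at roughly 10x the background amplitude
    with heavy-tailed transients; b and c: coloured AR(2) background with
    sporadic spikes (b spikier than c, deliberately confusable); d: strong
    10 Hz (alpha-band) oscillation; e: attenuated 10 Hz plus broadband noise.
    """
    return {
        1: ClassSynthParams(amplitude=100.0, osc_freq_hz=3.0, spike_rate=1.0,
                            spike_amp=0.5, noise_sd=15.0, spike_wave=True),
        2: ClassSynthParams(amplitude=0.0, spike_rate=0.8, spike_amp=4.0,
                            noise_sd=12.0),
        3: ClassSynthParams(amplitude=0.0, spike_rate=0.3, spike_amp=4.0,
                            noise_sd=12.0),
        4: ClassSynthParams(amplitude=50.0, osc_freq_hz=10.0, noise_sd=10.0),
        5: ClassSynthParams(amplitude=10.0, osc_freq_hz=10.0, noise_sd=12.0,
                            ar_coeffs=(0.3, 0.1)),
    }


@dataclass
class SynthConfig:
    """Configuration of the synthetic segment generator."""

    n_per_class: int = 100
    segment_len: int = DEFAULT_SEGMENT_LEN
    sampling_rate: float = DEFAULT_SAMPLING_RATE
    seed: int = 0
    class_params: dict = field(default_factory=default_class_params)

    def __post_init__(self):
        if self.n_per_class < 0:
            raise ValueError("n_per_class must be >= 0")
        if self.segment_len <= 0:
            raise ValueError("segment_len must be positive")
        for label, p in self.class_params.items():
            if p.spike_rate < 0 or p.noise_sd < 0:
                raise ValueError(f"negative rate/sd for class {label}")


def load_uci_csv(path, dialect: str = "auto", n_features: int = DEFAULT_SEGMENT_LEN,
                 ) -> SegmentSet:
    """Read a CSV in the public corpus dialect into a five-class SegmentSet.

    The dialect is: optional header row, optional leading id column (strings
    like ``X21.V1.791``), ``n_features`` numeric signal columns, and a final
    integer label column in 1..5.  Row order is preserved.

    Parameters
    ----------
    dialect
        ``"with_id"``, ``"without_id"``, or ``"auto"`` (treat the first
        column as an id iff it is non-numeric).
    """
    if dialect not in ("auto", "with_id", "without_id"):
        raise ValueError(f"unknown dialect {dialect!r}")
    try:
        df = pd.read_csv(path, header=None, dtype=str)
    except pd.errors.EmptyDataError:
        raise ValueError(f"empty CSV file: {path}") from None
    if df.shape[0] == 0:
        raise ValueError(f"empty CSV file: {path}")

    # Header detection: a header row has a non-numeric entry in its last
    # (label) column.
    def _is_number(s) -> bool:
        try:
            float(s)
            return True
        except (TypeError, ValueError):
            return False

    if not _is_number(df.iloc[0, df.shape[1] - 1]):
        df = df.iloc[1:].reset_index(drop=True)
        if df.shape[0] == 0:
            raise ValueError(f"CSV {path} contains a header but no data rows")

    if dialect == "auto":
        has_id = not _is_number(df.iloc[0, 0])
    else:
        has_id = dialect == "with_id"
    if has_id:
        df = df.iloc[:, 1:]

    expected = n_features + 1  # signals + label
    if df.shape[1] != expected:
        raise ValueError(
            f"expected {expected} data columns ({n_features} signals + label), "
            f"observed {df.shape[1]}"
        )

    try:
        values = df.to_numpy(dtype=float)
    except ValueError:
        # locate the offending row for a useful message
        for i in range(df.shape[0]):
            try:
                df.iloc[i].to_numpy(dtype=float)
            except ValueError:
                raise ValueError(f"malformed (non-numeric) row at index {i}") from None
        raise
    signals = values[:, :-1]
    labels = values[:, -1]
    if not np.all(labels == np.round(labels)):
        raise ValueError("label column contains non-integer values")
    return SegmentSet(signals=signals, labels=labels.astype(int))


def save_uci_csv(s: SegmentSet, path, header: bool = True) -> None:
    """Write a SegmentSet in the same CSV dialect (no id column)."""
    n = s.segment_len
    buf = io.StringIO()
    if header:
        buf.write(",".join([f"X{i + 1}" for i in range(n)] + ["y"]) + "\n")
    for row, lab in zip(s.signals, s.labels):
        buf.write(",".join(f"{v:.10g}" for v in row) + f",{lab}\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def segment_recordings(rec: RecordingSet, chunk_len: int = DEFAULT_SEGMENT_LEN,
                       sampling_rate: float = DEFAULT_SAMPLING_RATE) -> SegmentSet:
    """Cut recordings into non-overlapping fixed-length chunks.

    Each recording yields ``floor(length / chunk_len)`` chunks inheriting the
    recording's label; the trailing remainder is discarded (a 4097-sample
    recording at chunk_len 178 gives 23 chunks, dropping 3 samples).
    """
    if chunk_len <= 0:
        raise ValueError("chunk_len must be positive")
    if chunk_len > rec.recording_len:
        raise ValueError(
            f"chunk_len {chunk_len} exceeds recording length {rec.recording_len}"
        )
    k = rec.recording_len // chunk_len
    trimmed = rec.recordings[:, : k * chunk_len]
    signals = trimmed.reshape(rec.n_recordings * k, chunk_len)
    labels = np.repeat(rec.labels, k)
    return SegmentSet(signals=signals, labels=labels,
                      sampling_rate=sampling_rate)


def to_binary(s: SegmentSet) -> SegmentSet:
    """Relabel five-class data to seizure (1) vs non-seizure (0).

    Class 1 (ictal) keeps label 1; classes 2-5 map to 0.  Signals are
    untouched.  Refuses already-binary input rather than silently assuming
    idempotence.
    """
    if s.label_scheme != "five_class":
        raise ValueError("to_binary expects a five_class SegmentSet")
    labels = (s.labels == 1).astype(int)
    return SegmentSet(signals=s.signals.copy(), labels=labels,
                      label_scheme="binary", class_names=BINARY_CLASS_NAMES,
                      sampling_rate=s.sampling_rate)


def _spike_wave(phase: np.ndarray) -> np.ndarray:
    """Sharp spike-and-wave template: a narrow peak riding a slow wave.

    The peak is a periodic von-Mises-shaped pulse whose harmonic content
    decays quickly, so the template's energy stays near the 3 Hz
    fundamental rather than leaking into the alpha band.
    """
    slow = np.sin(phase)
    spike = np.exp(4.0 * (np.cos(phase) - 1.0)) - 0.2
    return 0.6 * slow + spike


def _ar2(rng: np.random.Generator, n: int, coeffs, sd: float) -> np.ndarray:
    """Stationary-ish AR(2) sample path with a short burn-in."""
    burn = 50
    e = rng.normal(0.0, sd, size=n + burn)
    x = np.zeros(n + burn)
    a1, a2 = coeffs
    for t in range(2, n + burn):
        x[t] = a1 * x[t - 1] + a2 * x[t - 2] + e[t]
    return x[burn:]


def _synth_segment(rng: np.random.Generator, p: ClassSynthParams,
                   n: int, fs: float) -> np.ndarray:
    t = np.arange(n) / fs
    x = _ar2(rng, n, p.ar_coeffs, p.noise_sd)
    if p.amplitude > 0 and p.osc_freq_hz > 0:
        phase = 2 * np.pi * p.osc_freq_hz * t + rng.uniform(0, 2 * np.pi)
        wave = _spike_wave(phase) if p.spike_wave else np.sin(phase)
        x = x + p.amplitude * wave
    n_spikes = rng.poisson(p.spike_rate * n / fs)
    for _ in range(n_spikes):
        center = rng.integers(0, n)
        width = rng.integers(2, 6)
        # heavy-tailed spike height (Student-t, 3 df)
        height = p.spike_amp * max(p.amplitude, p.noise_sd) * rng.standard_t(3)
        lo, hi = max(0, center - width), min(n, center + width + 1)
        full = np.hanning(2 * width + 1)
        offset = lo - (center - width)
        x[lo:hi] += height * full[offset:offset + (hi - lo)]
    return x


def synth_generate(cfg: SynthConfig) -> SegmentSet:
    """Generate a five-class synthetic SegmentSet.

    Deterministic under a fixed seed.  Class structure follows
    :func:`default_class_params` unless overridden in the config.
    """
    rng = np.random.default_rng(cfg.seed)
    signals, labels = [], []
    for label in sorted(cfg.class_params):
        p = cfg.class_params[label]
        for _ in range(cfg.n_per_class):
            signals.append(_synth_segment(rng, p, cfg.segment_len,
                                          cfg.sampling_rate))
            labels.append(label)
    if not signals:
        return SegmentSet(signals=np.empty((0, cfg.segment_len)),
                          labels=np.empty(0, dtype=int),
                          sampling_rate=cfg.sampling_rate)
    return SegmentSet(signals=np.stack(signals), labels=np.array(labels),
                      sampling_rate=cfg.sampling_rate)


def synth_localized_bursts(n_per_class: int, segment_len: int = DEFAULT_SEGMENT_LEN,
                           burst_len: int = 50, seed: int = 0,
                           sampling_rate: float = DEFAULT_SAMPLING_RATE):
    """Binary set whose seizure segments carry one localized spike burst.

    Seizure segments (label 1) are AR(2) background plus a high-amplitude
    3 Hz spike-wave burst confined to a random contiguous window of
    ``burst_len`` samples; non-seizure segments (label 0) are background
    only.  Returns ``(SegmentSet, windows)`` where ``windows[i]`` is the
    ``(start, stop)`` sample window of segment i's burst, or ``(-1, -1)``
    for background segments.  Intended for saliency-localization checks.
    """
    rng = np.random.default_rng(seed)
    p_bg = ClassSynthParams(noise_sd=12.0)
    signals, labels, windows = [], [], []
    for _ in range(n_per_class):
        x = _ar2(rng, segment_len, p_bg.ar_coeffs, p_bg.noise_sd)
        signals.append(x)
        labels.append(0)
        windows.append((-1, -1))
    for _ in range(n_per_class):
        x = _ar2(rng, segment_len, p_bg.ar_coeffs, p_bg.noise_sd)
        start = int(rng.integers(0, segment_len - burst_len + 1))
        t = np.arange(burst_len) / sampling_rate
        phase = 2 * np.pi * 3.0 * t + rng.uniform(0, 2 * np.pi)
        burst = 120.0 * _spike_wave(phase) * np.hanning(burst_len)
        x[start:start + burst_len] += burst
        signals.append(x)
        labels.append(1)
        windows.append((start, start + burst_len))
    s = SegmentSet(signals=np.stack(signals), labels=np.array(labels),
                   label_scheme="binary", class_names=BINARY_CLASS_NAMES,
                   sampling_rate=sampling_rate)
    return s, np.array(windows)


def stratified_split(s: SegmentSet, test_frac: float, seed: int):
    """Per-class random split into (train, test), proportions preserved.

    Every class contributes ``round(test_frac * n_class)`` test rows
    (at least 1); classes with fewer than 2 members are rejected.
    """
    if not 0 < test_frac < 1:
        raise ValueError("test_frac must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for label in np.unique(s.labels):
        idx = np.flatnonzero(s.labels == label)
        if idx.size < 2:
            raise ValueError(f"class {label} has fewer than 2 members")
        rng.shuffle(idx)
        n_test = min(max(1, round(test_frac * idx.size)), idx.size - 1)
        test_idx.append(idx[:n_test])
        train_idx.append(idx[n_test:])
    train_idx = np.sort(np.concatenate(train_idx))
    test_idx = np.sort(np.concatenate(test_idx))
    return s.subset(train_idx), s.subset(test_idx)
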