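"""Multichannel physiological recordings: reading, validation, preprocessing, windowing.

A recording bundles concurrent EEG/ECG/plethysmography traces with their
sampling rate(s) and an organ label per channel (BRAIN, HEART, LUNGS).
Two on-disk dialects are accepted: EDF (European Data Format) and a
delimited-text matrix (one header row of channel labels, one row per
sample, optional ``# fs=<Hz>`` comment line carrying the sampling rate).

Recordings whose channels were acquired at different rates (e.g. ECG at
2 kHz alongside 500 Hz EEG) are held in a ragged per-channel form until
:func:`lowpass_downsample` harmonizes them onto a single rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
from scipy import signal as _sig

logger = logging.getLogger(__name__)

ORGANS = ("BRAIN", "HEART", "LUNGS")


class RecordingError(ValueError):
    """Raised for unreadable or invalid recording inputs."""


@dataclass
class MultichannelRecording:
    """Samples x channels matrix with sampling rate(s) and organ labels.

    Parameters
    ----------
    data : ndarray of shape (n_samples, n_channels), or list of 1-D arrays
        Signal amplitudes (arbitrary per-channel units). A list of
        per-channel arrays is used only while channels still differ in
        sampling rate; all analysis operations require the uniform form.
    fs : float or ndarray
        Sampling rate in Hz; a per-channel array in the ragged case.
    channel_labels : list of str
    organ_map : mapping from channel label to organ name
    start_time : float
        Offset of the first sample in seconds.
    """

    data: object
    fs: object
    channel_labels: list
    organ_map: dict
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.channel_labels = list(self.channel_labels)
        self.organ_map = dict(self.organ_map)
        if self.is_uniform:
            self.data = np.asarray(self.data, dtype=float)
            if self.data.ndim != 2:
                raise RecordingError("uniform recording data must be 2-D (samples x channels)")
            self.fs = float(self.fs)
        else:
            self.data = [np.asarray(ch, dtype=float).ravel() for ch in self.data]
            self.fs = np.asarray(self.fs, dtype=float)
        self.validate()

    # -- basic geometry -------------------------------------------------
    @property
    def is_uniform(self) -> bool:
        return np.isscalar(self.fs) or (
            isinstance(self.fs, (int, float)) or getattr(self.fs, "ndim", 1) == 0
        )

    @property
    def n_channels(self) -> int:
        return len(self.channel_labels)

    @property
    def n_samples(self) -> int:
        if not self.is_uniform:
            raise RecordingError("n_samples is undefined for mixed-rate recordings")
        return self.data.shape[0]

    @property
    def duration_s(self) -> float:
        if self.is_uniform:
            return self.n_samples / self.fs
        return float(len(self.data[0]) / self.fs[0])

    def organ_of(self, label: str) -> str:
        return self.organ_map[label]

    def channels_of(self, organ: str) -> list:
        return [c for c in self.channel_labels if self.organ_map[c] == organ]

    def channel_data(self, label: str) -> np.ndarray:
        idx = self.channel_labels.index(label)
        return self.data[:, idx] if self.is_uniform else self.data[idx]

    def channel_fs(self, label: str) -> float:
        idx = self.channel_labels.index(label)
        return self.fs if self.is_uniform else float(self.fs[idx])

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        if self.n_channels < 1:
            raise RecordingError("recording must have at least one channel")
        if self.is_uniform:
            if self.data.shape[1] != self.n_channels:
                raise RecordingError(
                    f"data has {self.data.shape[1]} columns but "
                    f"{self.n_channels} channel labels"
                )
            if self.data.shape[0] < 1:
                raise RecordingError("recording must have at least one sample")
            columns = (self.data[:, k] for k in range(self.n_channels))
        else:
            if len(self.data) != self.n_channels or len(self.fs) != self.n_channels:
                raise RecordingError("ragged recording needs one trace and one rate per channel")
            if any(len(ch) < 1 for ch in self.data):
                raise RecordingError("recording must have at least one sample per channel")
            columns = iter(self.data)
        for label, col in zip(self.channel_labels, columns):
            bad = np.flatnonzero(~np.isfinite(col))
            if bad.size:
                raise RecordingError(
                    f"non-finite value in channel {label!r} at sample index {bad[0]}"
                )
        for label in self.channel_labels:
            if label not in self.organ_map:
                raise RecordingError(f"channel {label!r} has no organ assignment")
            if self.organ_map[label] not in ORGANS:
                raise RecordingError(
                    f"channel {label!r} mapped to unknown organ {self.organ_map[label]!r}"
                )

    def organ_counts(self) -> dict:
        counts = {o: 0 for o in ORGANS}
        for c in self.channel_labels:
            counts[self.organ_map[c]] += 1
        return counts


@dataclass(frozen=True)
class WindowSpec:
    """Analysis window: ``length_s`` seconds with ``overlap_s`` overlap (0 = consecutive)."""

    length_s: float = 10.0
    overlap_s: float = 0.0

    def __post_init__(self) -> None:
        if self.length_s <= 0:
            raise ValueError("window length must be positive")
        if not (0 <= self.overlap_s < self.length_s):
            raise ValueError("overlap must satisfy 0 <= overlap < length")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_edf_header_rates(path: Path) -> tuple[list, np.ndarray]:
    """Per-signal labels and sampling rates straight from the EDF header."""
    with open(path, "rb") as fh:
        header = fh.read(256)
        if len(header) < 256:
            raise RecordingError(f"unreadable EDF file: {path}")
        try:
            record_dur = float(header[244:252].decode("ascii").strip())
            n_signals = int(header[252:256].decode("ascii").strip())
        except (UnicodeDecodeError, ValueError) as exc:
            raise RecordingError(f"unreadable EDF header in {path}: {exc}") from exc
        sig_hdr = fh.read(n_signals * 256)
    labels = [
        sig_hdr[16 * k : 16 * (k + 1)].decode("ascii", "replace").strip()
        for k in range(n_signals)
    ]
    off = n_signals * (16 + 80 + 8 + 8 + 8 + 8 + 8 + 80)
    n_samps = np.array(
        [
            int(sig_hdr[off + 8 * k : off + 8 * (k + 1)].decode("ascii").strip())
            for k in range(n_signals)
        ]
    )
    return labels, n_samps / record_dur


def _read_edf(path: Path, organ_map: Mapping) -> MultichannelRecording:
    import mne

    labels, rates = _read_edf_header_rates(path)
    keep = [(lab, r) for lab, r in zip(labels, rates) if lab in organ_map] or list(
        zip(labels, rates)
    )
    traces: dict = {}
    # mne resamples mixed-rate files onto one grid; reading one rate-group at a
    # time keeps every channel at its acquired rate.
    for rate in sorted({r for _, r in keep}):
        include = [lab for lab, r in keep if r == rate]
        raw = mne.io.read_raw_edf(path, include=include, preload=True, verbose="error")
        for lab in include:
            traces[lab] = raw.get_data(picks=[lab])[0]
    ordered = [lab for lab, _ in keep]
    fs = np.array([r for _, r in keep])
    if np.all(fs == fs[0]):
        data = np.column_stack([traces[lab] for lab in ordered])
        return MultichannelRecording(data, float(fs[0]), ordered, dict(organ_map) or {})
    return MultichannelRecording([traces[lab] for lab in ordered], fs, ordered, dict(organ_map))


def _read_text(path: Path, organ_map: Mapping, fs: float | None) -> MultichannelRecording:
    import pandas as pd

    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
        second = fh.readline()
    if first.startswith("#"):
        for token in first[1:].replace(",", " ").split():
            if token.startswith("fs="):
                fs = float(token[3:])
        skiprows = 1
        header_line = second
    else:
        skiprows = 0
        header_line = first
    if fs is None:
        raise RecordingError(
            f"no sampling rate for {path}: pass fs= or include a '# fs=<Hz>' header line"
        )
    sep = "\t" if "\t" in header_line else ","
    frame = pd.read_csv(path, sep=sep, skiprows=skiprows, float_precision="round_trip")
    labels = [str(c) for c in frame.columns]
    data = frame.to_numpy(dtype=float)
    return MultichannelRecording(data, float(fs), labels, dict(organ_map))


def read_recording(
    path, organ_map: Mapping, fs: float | None = None
) -> MultichannelRecording:
    """Read an EDF or delimited-text recording and validate it.

    ``organ_map`` must cover every channel retained; channels named in
    ``organ_map`` but absent from the file raise :class:`RecordingError`.
    """
    path = Path(path)
    if not path.exists():
        raise RecordingError(f"no such file: {path}")
    with open(path, "rb") as fh:
        magic = fh.read(8)
    is_edf = path.suffix.lower() == ".edf" or magic[:1] == b"0"
    rec = _read_edf(path, organ_map) if is_edf else _read_text(path, organ_map, fs)
    missing = [c for c in organ_map if c not in rec.channel_labels]
    if missing:
        raise RecordingError(
            f"channels {missing} named in organ_map are absent from {path.name} "
            f"(file has {rec.channel_labels})"
        )
    return rec


def write_recording(rec: MultichannelRecording, path, delimiter: str = "\t") -> None:
    """Write a uniform-rate recording in the delimited-text dialect (round-trips exactly)."""
    if not rec.is_uniform:
        raise RecordingError("write_recording requires a single-rate recording")
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# fs={rec.fs!r}\n")
        fh.write(delimiter.join(rec.channel_labels) + "\n")
        for row in rec.data:
            fh.write(delimiter.join(repr(float(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def lowpass_downsample(
    rec: MultichannelRecording,
    cutoff_hz: float = 200.0,
    order: int = 4,
    target_fs: float = 500.0,
    zero_phase: bool = False,
    filter_passthrough: bool = False,
) -> MultichannelRecording:
    """Butterworth low-pass + integer decimation onto a common sampling rate.

    Channels already at ``target_fs`` pass through unfiltered (set
    ``filter_passthrough`` to low-pass them too). Filtering is causal
    (forward-only) by default; ``zero_phase`` switches to filtfilt.
    """
    if cutoff_hz >= target_fs / 2:
        raise RecordingError(
            f"cutoff {cutoff_hz} Hz is at or above the target Nyquist {target_fs / 2} Hz"
        )
    labels = rec.channel_labels
    rates = (
        [rec.fs] * rec.n_channels if rec.is_uniform else [float(r) for r in rec.fs]
    )
    out = []
    min_len = None
    for k, (lab, fs_k) in enumerate(zip(labels, rates)):
        x = rec.data[:, k] if rec.is_uniform else rec.data[k]
        if fs_k == target_fs and not filter_passthrough:
            y = x
        else:
            if cutoff_hz >= fs_k / 2:
                raise RecordingError(
                    f"cutoff {cutoff_hz} Hz >= Nyquist of channel {lab!r} ({fs_k / 2} Hz)"
                )
            sos = _sig.butter(order, cutoff_hz, btype="low", fs=fs_k, output="sos")
            y = _sig.sosfiltfilt(sos, x) if zero_phase else _sig.sosfilt(sos, x)
            if fs_k != target_fs:
                ratio = fs_k / target_fs
                if abs(ratio - round(ratio)) > 1e-9 or ratio < 1:
                    raise RecordingError(
                        f"target rate {target_fs} Hz must divide channel {lab!r} "
                        f"rate {fs_k} Hz for decimation"
                    )
                y = y[:: int(round(ratio))]
        out.append(np.asarray(y, dtype=float))
        min_len = len(y) if min_len is None else min(min_len, len(y))
    data = np.column_stack([y[:min_len] for y in out])
    return MultichannelRecording(
        data, float(target_fs), labels, rec.organ_map, rec.start_time
    )


def segment_windows(
    rec: MultichannelRecording, spec: WindowSpec = WindowSpec()
) -> Iterator[tuple]:
    """Yield ``(window_index, start_s, block)`` over consecutive analysis windows.

    Blocks are exactly ``length_s * fs`` samples; a trailing partial window
    is dropped (and logged). With ``overlap_s`` = 0 the blocks tile a prefix
    of the recording with no gaps.
    """
    if not rec.is_uniform:
        raise RecordingError("segment_windows requires a harmonized (single-rate) recording")
    win = int(round(spec.length_s * rec.fs))
    step = int(round((spec.length_s - spec.overlap_s) * rec.fs))
    n = rec.n_samples
    if n < win:
        raise RecordingError(
            f"recording of {n} samples is shorter than one {win}-sample window"
        )
    idx = 0
    start = 0
    while start + win <= n:
        yield idx, rec.start_time + start / rec.fs, rec.data[start : start + win]
        idx += 1
        start += step
    if start < n:
        logger.info(
            "dropped trailing partial window of %.2f s", (n - start) / rec.fs
        )


def count_windows(n_samples: int, fs: float, spec: WindowSpec) -> int:
    win = int(round(spec.length_s * fs))
    step = int(round((spec.length_s - spec.overlap_s) * fs))
    if n_samples < win:
        return 0
    return (n_samples - win) // step + 1
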