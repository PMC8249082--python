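"""Time-resolved in-band connectivity: series extraction, smoothing, reference bands.

For a chosen interaction and frequency band, each analysis window
contributes one value — the mean of its significant in-band squared-GPDC
values over the contributing channel pairs, or 0 when none are
significant (consistent with the zero rule used for band profiles; an
option treats such windows as gaps instead). The series is smoothed with
a centered 9-point moving average by default, so each smoothed point
summarizes 90 s of raw data at the 10-s window setting. Group-level
"reference bands" (mean +/- SEM envelopes of pooled ssGPDC at the same
band) provide the backdrop against which peri-event excursions are read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .aggregation import WindowedConnectivity, _in_band, pool_organ_pair


@dataclass
class ConnectivityTimeSeries:
    """Per-window mean in-band ssGPDC for one organ pair, with event annotations."""

    times_s: np.ndarray
    values: np.ndarray
    pair: tuple
    band: tuple
    events: list = field(default_factory=list)  # (time_s, label) pairs, pure metadata
    smoothed: bool = False

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times_s.shape != self.values.shape:
            raise ValueError("times and values must have the same length")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.times_s,
                "value": self.values,
                "from_organ": self.pair[0],
                "to_organ": self.pair[1],
                "band_low_hz": self.band[0],
                "band_high_hz": self.band[1],
            }
        )


@dataclass(frozen=True)
class ReferenceBand:
    """Group-level mean +/- SEM envelope of pooled ssGPDC at one band."""

    group: str
    mean: float
    sem: float
    band: tuple


def extract_band_timeseries(
    conn: WindowedConnectivity,
    pair: tuple,
    band: tuple,
    empty_as_nan: bool = False,
) -> ConnectivityTimeSeries:
    """Per-window mean of significant in-band values; 0 (or NaN) when none."""
    fsel = _in_band(conn.grid, band)
    mask = conn.mask
    chan_pairs = conn.channel_pairs(pair)
    W = conn.n_windows
    values = np.zeros(W)
    fill = np.nan if empty_as_nan else 0.0
    for w in range(W):
        vals = [
            conn.gpdc[w, i, j, fsel][mask[w, i, j, fsel]] for i, j in chan_pairs
        ]
        vals = np.concatenate(vals) if vals else np.array([])
        values[w] = vals.mean() if vals.size else fill
    return ConnectivityTimeSeries(
        times_s=conn.times_s, values=values, pair=tuple(pair), band=tuple(band),
        events=list(conn.meta.get("events", [])),
    )


def smooth_series(series: ConnectivityTimeSeries, k: int = 4) -> ConnectivityTimeSeries:
    """Centered moving average of half-width k (k = 4 gives the 9-point default).

    At the edges the window shrinks symmetrically to the available
    points, so timestamps are unchanged and a constant series is returned
    identically. ``k = 0`` is the identity.
    """
    if k < 0:
        raise ValueError("half-width k must be >= 0")
    v = series.values
    n = v.size
    out = np.empty_like(v)
    for i in range(n):
        h = min(k, i, n - 1 - i)
        window = v[i - h : i + h + 1]
        finite = window[np.isfinite(window)]
        out[i] = finite.mean() if finite.size else np.nan
    return ConnectivityTimeSeries(
        times_s=series.times_s, values=out, pair=series.pair, band=series.band,
        events=list(series.events), smoothed=True,
    )


def reference_bands(
    groups: dict,
    band: tuple,
    pair: tuple,
) -> list:
    """Mean +/- SEM reference envelope per group at the selected band.

    ``groups`` maps a group label to a :class:`WindowedConnectivity` (or a
    sequence of them, one per recording). Groups with empty pools are
    omitted with a warning.
    """
    import warnings

    out = []
    for label, conn in groups.items():
        pooled = pool_organ_pair(conn, pair, band)
        if pooled.size == 0:
            warnings.warn(f"group {label!r}: no significant values in band {band}; omitted")
            continue
        sem = float(pooled.std(ddof=1) / np.sqrt(pooled.size)) if pooled.size > 1 else 0.0
        out.append(ReferenceBand(group=label, mean=float(pooled.mean()), sem=sem,
                                 band=tuple(band)))
    return out


def series_table(
    raw: ConnectivityTimeSeries, smoothed: ConnectivityTimeSeries
) -> pd.DataFrame:
    """Tidy export: time, raw and smoothed value, pair, band."""
    frame = raw.to_frame().rename(columns={"value": "raw_value"})
    frame["smoothed_value"] = smoothed.values
    return frame


def read_events(path) -> list:
    """Two-column text events file: onset_s <tab-or-comma> label."""
    events = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", "\t").split("\t")
            events.append((float(parts[0]), parts[1].strip() if len(parts) > 1 else "event"))
    return events
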