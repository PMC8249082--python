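"""Pooling channel-level ssGPDC into organ-pair frequency-band profiles.

The six ordered inter-organ interactions (BRAIN->HEART, HEART->BRAIN,
BRAIN->LUNGS, LUNGS->BRAIN, HEART->LUNGS, LUNGS->HEART) are summarized by
pooling every significant squared-GPDC value across all contributing
channel pairs, all in-band grid frequencies, and all windows into one
sample per (interaction, band). The band grid is 10 Hz consecutive bands
over 1-200 Hz by default, with bands containing 60 Hz mains harmonics
(50-60, 110-120, 170-180 Hz) excluded. A band with no significant values
is assigned a mean of zero (flagged ``zero_assigned``) rather than being
dropped — absence of significant coupling is itself the datum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations
from typing import Sequence

import numpy as np
import pandas as pd

from .gpdc import FrequencyGrid
from .recording import ORGANS

INTERACTIONS = [p for p in permutations(ORGANS, 2)]


@dataclass
class WindowedConnectivity:
    """Stacked per-window GPDC values, p-values and significance masks.

    Attributes
    ----------
    gpdc : ndarray (W, D, D, F)
        Squared GPDC per window; entry (w, i, j, f) = flow j -> i.
    p_values : ndarray (W, D, D, F)
    alpha : float
    times_s : ndarray (W,)
        Window start times.
    """

    gpdc: np.ndarray
    p_values: np.ndarray
    alpha: float
    grid: FrequencyGrid
    channel_labels: list
    organ_map: dict
    times_s: np.ndarray
    window_indices: np.ndarray = None
    excluded_windows: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.gpdc = np.asarray(self.gpdc, dtype=float)
        self.p_values = np.asarray(self.p_values, dtype=float)
        self.times_s = np.asarray(self.times_s, dtype=float)
        if self.window_indices is None:
            self.window_indices = np.arange(self.gpdc.shape[0])

    @property
    def mask(self) -> np.ndarray:
        return self.p_values < self.alpha

    @property
    def n_windows(self) -> int:
        return self.gpdc.shape[0]

    def channel_pairs(self, pair: tuple) -> list:
        """(to_index i, from_index j) channel combinations realizing an organ pair."""
        from_organ, to_organ = pair
        for organ in pair:
            if organ not in ORGANS:
                raise ValueError(f"unknown organ {organ!r}")
        idx = {lab: k for k, lab in enumerate(self.channel_labels)}
        froms = [idx[c] for c in self.channel_labels if self.organ_map[c] == from_organ]
        tos = [idx[c] for c in self.channel_labels if self.organ_map[c] == to_organ]
        return [(i, j) for j in froms for i in tos if i != j]


@dataclass(frozen=True)
class BandGrid:
    """Consecutive half-open frequency bands (low, high], some excluded as mains harmonics."""

    bands: tuple
    excluded: tuple

    @property
    def retained(self) -> list:
        return [b for b, ex in zip(self.bands, self.excluded) if not ex]

    def is_excluded(self, band: tuple) -> bool:
        return self.excluded[self.bands.index(tuple(band))]


def define_bands(width_hz: float = 10.0, f_max: float = 200.0,
                 line_hz: float = 60.0) -> BandGrid:
    """Partition (0, f_max] into ``width_hz`` bands, flagging mains-harmonic bands.

    A band (low, high] is excluded when it contains a positive multiple of
    ``line_hz``; with the defaults that is (50,60], (110,120] and (170,180].
    ``line_hz = 0`` disables exclusion.
    """
    n = f_max / width_hz
    if abs(n - round(n)) > 1e-9:
        raise ValueError(f"band width {width_hz} does not divide f_max {f_max}")
    n = int(round(n))
    bands = tuple((k * width_hz, (k + 1) * width_hz) for k in range(n))
    if line_hz and line_hz > 0:
        excluded = tuple(
            any(lo < m * line_hz <= hi for m in range(1, int(f_max / line_hz) + 1))
            for lo, hi in bands
        )
    else:
        excluded = (False,) * n
    return BandGrid(bands=bands, excluded=excluded)


@dataclass
class InteractionProfile:
    """Per-band pooled mean +/- SEM of ssGPDC for one ordered organ pair."""

    organ_pair: tuple
    bands: list
    n_values: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    zero_assigned: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "from_organ": self.organ_pair[0],
                "to_organ": self.organ_pair[1],
                "band_low_hz": [b[0] for b in self.bands],
                "band_high_hz": [b[1] for b in self.bands],
                "n": self.n_values,
                "mean": self.mean,
                "sem": self.sem,
                "zero_assigned": self.zero_assigned,
            }
        )


def _in_band(grid: FrequencyGrid, band: tuple) -> np.ndarray:
    lo, hi = band
    return (grid.freqs > lo) & (grid.freqs <= hi)


def pool_organ_pair(
    conn: WindowedConnectivity | Sequence[WindowedConnectivity],
    pair: tuple,
    band: tuple,
) -> np.ndarray:
    """Multiset of significant squared-GPDC values for one organ pair and band.

    Pools over all channel-pair combinations realizing the ordered organ
    pair, all grid frequencies inside the half-open band, and all windows
    (and, when a sequence of connectivity results is given, all
    recordings). Every channel-pair value counts as one sample. The
    result may be empty.
    """
    if pair[0] == pair[1]:
        raise ValueError("organ pair must be inter-organ (from != to)")
    conns = [conn] if isinstance(conn, WindowedConnectivity) else list(conn)
    out = []
    for c in conns:
        fsel = _in_band(c.grid, band)
        mask = c.mask
        for i, j in c.channel_pairs(pair):
            vals = c.gpdc[:, i, j, fsel]
            out.append(vals[mask[:, i, j, fsel]])
    return np.concatenate(out) if out else np.array([])


def _summarize(values: np.ndarray) -> tuple:
    n = values.size
    if n == 0:
        return 0, 0.0, 0.0, True
    if n == 1:
        return 1, float(values[0]), 0.0, False
    return n, float(values.mean()), float(values.std(ddof=1) / np.sqrt(n)), False


def band_profile(
    conn: WindowedConnectivity | Sequence[WindowedConnectivity],
    pair: tuple,
    band_grid: BandGrid,
) -> InteractionProfile:
    """Mean +/- SEM of pooled ssGPDC per retained band for one organ pair.

    Empty bands get mean 0, SEM 0 and ``zero_assigned``; a single-value
    band reports SEM 0 (n = 1 convention). Excluded (mains-harmonic)
    bands carry no profile entry.
    """
    bands = band_grid.retained
    n_values = np.zeros(len(bands), dtype=int)
    mean = np.zeros(len(bands))
    sem = np.zeros(len(bands))
    zero = np.zeros(len(bands), dtype=bool)
    for k, band in enumerate(bands):
        n_values[k], mean[k], sem[k], zero[k] = _summarize(
            pool_organ_pair(conn, pair, band)
        )
    return InteractionProfile(
        organ_pair=tuple(pair), bands=bands, n_values=n_values,
        mean=mean, sem=sem, zero_assigned=zero,
    )


def fullband_average(
    conn: WindowedConnectivity | Sequence[WindowedConnectivity],
    pair: tuple,
    band_grid: BandGrid | None = None,
) -> dict:
    """Pooled mean +/- SEM over the full spectrum, excluded bands' frequencies omitted."""
    if band_grid is None:
        band_grid = define_bands()
    pooled = pool_full_spectrum(conn, pair, band_grid)
    n, mean, sem, zero = _summarize(pooled)
    return {"from_organ": pair[0], "to_organ": pair[1], "n": n,
            "mean": mean, "sem": sem, "zero_assigned": zero}


def pool_full_spectrum(
    conn: WindowedConnectivity | Sequence[WindowedConnectivity],
    pair: tuple,
    band_grid: BandGrid,
) -> np.ndarray:
    """Pooled ssGPDC sample over all retained bands (the full-spectrum pool)."""
    parts = [pool_organ_pair(conn, pair, band) for band in band_grid.retained]
    return np.concatenate(parts) if parts else np.array([])


def profile_table(
    conn: WindowedConnectivity | Sequence[WindowedConnectivity],
    band_grid: BandGrid,
    pairs: Sequence[tuple] = None,
) -> pd.DataFrame:
    """Tidy profile table over all (or given) inter-organ interactions."""
    pairs = INTERACTIONS if pairs is None else pairs
    frames = [band_profile(conn, pair, band_grid).to_frame() for pair in pairs]
    return pd.concat(frames, ignore_index=True)


def significance_fraction(
    conn: WindowedConnectivity | Sequence[WindowedConnectivity],
    band_grid: BandGrid,
    pairs: Sequence[tuple] = None,
) -> pd.DataFrame:
    """Fraction of GPDC values significant per (interaction, band).

    Also exports the complementary percentage rendered *not* significant,
    a data-quality diagnostic for each interaction.
    """
    pairs = INTERACTIONS if pairs is None else pairs
    conns = [conn] if isinstance(conn, WindowedConnectivity) else list(conn)
    rows = []
    for pair in pairs:
        for band in band_grid.retained:
            n_sig = 0
            n_tot = 0
            for c in conns:
                fsel = _in_band(c.grid, band)
                for i, j in c.channel_pairs(pair):
                    m = c.mask[:, i, j, fsel]
                    n_sig += int(m.sum())
                    n_tot += m.size
            frac = n_sig / n_tot if n_tot else np.nan
            rows.append(
                {
                    "from_organ": pair[0], "to_organ": pair[1],
                    "band_low_hz": band[0], "band_high_hz": band[1],
                    "n_total": n_tot, "n_significant": n_sig,
                    "fraction_significant": frac,
                    "pct_not_significant": 100.0 * (1.0 - frac) if n_tot else np.nan,
                }
            )
    return pd.DataFrame(rows)
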