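"""Basic figures: band profiles and smoothed connectivity series."""

from __future__ import annotations

from typing import Sequence

import numpy as np


def plot_profiles(profiles: dict, ax=None):
    """Overlay per-group band profiles (mean +/- SEM vs band center frequency).

    ``profiles`` maps a group label to an
    :class:`~physioconn.aggregation.InteractionProfile`.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for label, prof in profiles.items():
        centers = np.array([(lo + hi) / 2 for lo, hi in prof.bands])
        ax.errorbar(centers, prof.mean, yerr=prof.sem, marker="o", capsize=3,
                    label=label)
    first = next(iter(profiles.values()))
    ax.set_xlabel("frequency band center (Hz)")
    ax.set_ylabel("mean ssGPDC")
    ax.set_title(f"{first.organ_pair[0]} → {first.organ_pair[1]}")
    ax.legend()
    return ax


def plot_series(series, reference: Sequence = (), ax=None):
    """Smoothed connectivity series with event markers and reference envelopes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(series.times_s / 3600.0, series.values, lw=1.0, color="k")
    for onset, label in series.events:
        ax.axvline(onset / 3600.0, color="m", lw=0.8, alpha=0.7)
    for ref in reference:
        ax.axhspan(ref.mean - ref.sem, ref.mean + ref.sem, alpha=0.3, label=ref.group)
    ax.set_xlabel("time (h)")
    ax.set_ylabel("smoothed ssGPDC")
    ax.set_title(
        f"{series.pair[0]} → {series.pair[1]} "
        f"({series.band[0]:g}-{series.band[1]:g} Hz)"
    )
    if reference:
        ax.legend()
    return ax
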