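"""Generalized partial directed coherence (GPDC) from a fitted MVAR model.

GPDC is a frequency-domain, column-normalized measure of *direct* directed
influence. From the lag coefficients the spectral transfer structure is

    Abar(f) = I - sum_{r=1..p} A_r exp(-i 2 pi f r / fs)

and the squared GPDC from channel j into channel i is

    |pibar_ij(f)|^2 = (|Abar_ij(f)|^2 / sigma_i^2)
                      / sum_k (|Abar_kj(f)|^2 / sigma_k^2)

where sigma_k^2 are the innovation variances. The normalization by the
innovation variances makes the measure invariant to rescaling any single
channel, so signals of vastly different physical magnitude (EEG in uV,
plethysmography in chamber-pressure units) are directly comparable.
Columns sum to one over the receiving index: sum_i |pibar_ij(f)|^2 = 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .mvar import MVARModel

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FrequencyGrid:
    """Ordered evaluation frequencies (Hz) bounded by the Nyquist rate."""

    freqs: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "freqs", np.asarray(self.freqs, dtype=float))
        f = self.freqs
        if f.ndim != 1 or f.size == 0:
            raise ValueError("frequency grid must be a non-empty 1-D array")
        if f[0] <= 0 or np.any(np.diff(f) <= 0):
            raise ValueError("frequencies must be strictly increasing and positive")
        if f[-1] > self.fs / 2 + 1e-9:
            raise ValueError(f"max frequency {f[-1]} exceeds Nyquist {self.fs / 2}")

    @classmethod
    def default(cls, fs: float = 500.0, f_min: float = 1.0, f_max: float = 200.0,
                spacing: float = 1.0) -> "FrequencyGrid":
        """1 Hz grid from 1 to 200 Hz at fs = 500 Hz unless overridden."""
        n = int(round((f_max - f_min) / spacing)) + 1
        return cls(f_min + spacing * np.arange(n), fs)

    @property
    def n_freqs(self) -> int:
        return self.freqs.size


@dataclass
class GPDCSpectrum:
    """Squared GPDC on a grid: ``values[i, j, f]`` = influence j -> i at freqs[f].

    Diagonal (self) entries are computed for completeness but are never
    interpreted as inter-organ flow downstream.
    """

    values: np.ndarray  # (D, D, F)
    grid: FrequencyGrid
    window_index: int = 0

    @property
    def dim(self) -> int:
        return self.values.shape[0]


def spectral_transfer(model: MVARModel, grid: FrequencyGrid) -> np.ndarray:
    """Complex spectral transfer structure Abar(f), shape (D, D, F)."""
    if abs(grid.fs - model.fs) > 1e-9:
        raise ValueError(f"grid fs {grid.fs} != model fs {model.fs}")
    p, D = model.order, model.dim
    omega = 2.0 * np.pi * grid.freqs / model.fs  # (F,)
    lags = np.arange(1, p + 1)
    phase = np.exp(-1j * np.outer(omega, lags))  # (F, p)
    A_f = np.einsum("fr,rij->ijf", phase, model.coeffs)
    out = -A_f
    idx = np.arange(D)
    out[idx, idx, :] += 1.0
    return out


def compute_gpdc(model: MVARModel, grid: FrequencyGrid) -> GPDCSpectrum:
    """Squared GPDC for every directed channel pair at every grid frequency.

    Satisfies the column normalization sum_i values[i, j, f] = 1 and exact
    structural zeros: if A_r[i, j] = 0 for all lags (no j -> i coupling and
    i != j), then values[i, j, f] = 0 at every frequency.
    """
    sigma2 = model.sigma2
    if np.any(sigma2 <= 0):
        raise ValueError("innovation variances must be strictly positive")
    A_bar = spectral_transfer(model, grid)
    num = (A_bar.real**2 + A_bar.imag**2) / sigma2[:, None, None]
    denom = num.sum(axis=0, keepdims=True)  # per (j, f)
    zero_cols = denom[0] == 0.0
    if np.any(zero_cols):
        logger.warning(
            "spectral transfer column numerically zero for %d (channel, freq) cells; "
            "GPDC set to NaN there",
            int(zero_cols.sum()),
        )
        denom = np.where(denom == 0.0, np.nan, denom)
    return GPDCSpectrum(values=num / denom, grid=grid, window_index=model.window_index)
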