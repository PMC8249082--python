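"""Nonparametric group comparison of pooled ssGPDC samples.

All comparisons use the two-sided Mann-Whitney-Wilcoxon rank-sum test:
exact enumeration when the smaller sample has at most 8 values and there
are no ties, the tie-corrected normal approximation otherwise. Stars
follow the reporting rule used throughout the package: ``*`` for
p < 0.05, ``**`` for p < 0.001. No multiple-comparison correction is
applied across bands or interactions by default — each (interaction,
band) cell is reported at its raw p-value; an optional
Benjamini-Hochberg adjustment is available but off by default, and
per-band p-values should be read accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as _st

from .aggregation import (
    INTERACTIONS,
    BandGrid,
    WindowedConnectivity,
    pool_full_spectrum,
    pool_organ_pair,
)

EXACT_MAX = 8


def _stars(p: float) -> str:
    if p < 0.001:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class ComparisonResult:
    """One rank-sum comparison between two pooled ssGPDC samples."""

    unit: object  # band tuple or "full-spectrum"
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    u_statistic: float
    p_value: float
    testable: bool = True

    @property
    def stars(self) -> str:
        return _stars(self.p_value) if self.testable else ""


def mannwhitney(
    sample_a: np.ndarray,
    sample_b: np.ndarray,
    unit: object = "full-spectrum",
    labels: tuple = ("A", "B"),
) -> ComparisonResult:
    """Two-sided Mann-Whitney-Wilcoxon rank-sum test on two value pools.

    An empty sample makes the comparison not-testable (mirrors
    interactions with too few significant values to compare) rather than
    raising.
    """
    a = np.asarray(sample_a, dtype=float).ravel()
    b = np.asarray(sample_b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        return ComparisonResult(
            unit=unit, group_a=labels[0], group_b=labels[1],
            n_a=a.size, n_b=b.size, u_statistic=np.nan, p_value=np.nan,
            testable=False,
        )
    no_ties = np.unique(np.concatenate([a, b])).size == a.size + b.size
    method = "exact" if (min(a.size, b.size) <= EXACT_MAX and no_ties) else "asymptotic"
    res = _st.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return ComparisonResult(
        unit=unit, group_a=labels[0], group_b=labels[1],
        n_a=a.size, n_b=b.size,
        u_statistic=float(res.statistic), p_value=float(res.pvalue),
    )


def compare_groups_per_band(
    group_a: Sequence[WindowedConnectivity] | WindowedConnectivity,
    group_b: Sequence[WindowedConnectivity] | WindowedConnectivity,
    pair: tuple,
    band_grid: BandGrid,
    labels: tuple = ("A", "B"),
) -> list:
    """One rank-sum test per retained band for one interaction; untestable bands flagged."""
    return [
        mannwhitney(
            pool_organ_pair(group_a, pair, band),
            pool_organ_pair(group_b, pair, band),
            unit=band, labels=labels,
        )
        for band in band_grid.retained
    ]


def compare_groups_full_spectrum(
    group_a, group_b, band_grid: BandGrid, labels: tuple = ("A", "B"),
    pairs: Sequence[tuple] = None,
) -> pd.DataFrame:
    """Full-spectrum rank-sum comparison per interaction (the genotype-contrast table)."""
    pairs = INTERACTIONS if pairs is None else pairs
    rows = []
    for pair in pairs:
        res = mannwhitney(
            pool_full_spectrum(group_a, pair, band_grid),
            pool_full_spectrum(group_b, pair, band_grid),
            labels=labels,
        )
        rows.append(
            {
                "from_organ": pair[0], "to_organ": pair[1],
                "n_a": res.n_a, "n_b": res.n_b,
                "u_statistic": res.u_statistic, "p_value": res.p_value,
                "stars": res.stars, "testable": res.testable,
            }
        )
    return pd.DataFrame(rows)


def compare_interaction_pairs(
    group: Sequence[WindowedConnectivity] | WindowedConnectivity,
    band_grid: BandGrid,
    pairs: Sequence[tuple] = None,
) -> pd.DataFrame:
    """Pairwise rank-sum p-values between the interactions within one group.

    Returns a symmetric-off-diagonal matrix (diagonal empty) over the
    full-spectrum pools; untestable cells are NaN.
    """
    pairs = INTERACTIONS if pairs is None else pairs
    names = [f"{a}->{b}" for a, b in pairs]
    pools = {name: pool_full_spectrum(group, pair, band_grid)
             for name, pair in zip(names, pairs)}
    mat = pd.DataFrame(np.nan, index=names, columns=names)
    for na, nb in combinations(names, 2):
        res = mannwhitney(pools[na], pools[nb], labels=(na, nb))
        if res.testable:
            mat.loc[na, nb] = mat.loc[nb, na] = res.p_value
    return mat


def select_discriminative_band(results: Sequence[ComparisonResult]) -> tuple:
    """Band with the minimum rank-sum p-value; ties break toward lower frequency.

    This is the band-selection rule for the peri-event dynamics: use the
    band where the two groups' ssGPDC profiles differ the most.
    """
    testable = [r for r in results if r.testable and np.isfinite(r.p_value)]
    if not testable:
        raise ValueError("no testable band")
    best = min(testable, key=lambda r: (r.p_value, r.unit[0]))
    return tuple(best.unit)


def band_comparison_table(
    group_a, group_b, band_grid: BandGrid, labels: tuple = ("A", "B"),
    pairs: Sequence[tuple] = None,
) -> pd.DataFrame:
    """Rows = interactions, columns = bands, cells = p-value with star annotation."""
    pairs = INTERACTIONS if pairs is None else pairs
    cols = {f"{int(lo)}-{int(hi)} Hz": (lo, hi) for lo, hi in band_grid.retained}
    out = {}
    for pair in pairs:
        row = {}
        results = compare_groups_per_band(group_a, group_b, pair, band_grid, labels)
        for (name, _), res in zip(cols.items(), results):
            row[name] = (
                f"{res.p_value:.3g}{res.stars}" if res.testable else "n/a"
            )
        out[f"{pair[0]}->{pair[1]}"] = row
    return pd.DataFrame(out).T


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """Optional BH-adjusted p-values (off by default everywhere; provided for sensitivity)."""
    p = np.asarray(p_values, dtype=float)
    ok = np.isfinite(p)
    adj = np.full_like(p, np.nan)
    if ok.sum():
        adj[ok] = _st.false_discovery_control(p[ok], method="bh")
    return adj
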