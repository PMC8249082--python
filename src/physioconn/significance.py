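"""Per-value significance testing of GPDC: surrogate and asymptotic backends.

Only values that pass the per-window test at P < alpha ("ssGPDC") are
pooled into organ-level statistics downstream. Two backends share the
same mask semantics (``significant`` iff ``p < alpha``, strictly):

* ``surrogate`` (default): each channel of the window is independently
  circularly shifted by a random offset of at least p samples, which
  destroys cross-channel coupling while preserving every channel's
  autospectrum; the MVAR fit and GPDC are recomputed per surrogate and
  the p-value is the standard add-one empirical tail
  ``(1 + #{null >= observed}) / (1 + n_surrogates)``.
* ``asymptotic``: plug-in large-sample null for the spectral-transfer
  numerator under zero coupling. The OLS coefficient estimates of the
  j -> i lag polynomial are jointly Gaussian with covariance
  sigma_i^2 V_j (V_j the per-channel block of the inverse Gram matrix),
  so |Abar_ij(f)|^2 is a two-term chi-square mixture whose survival
  function is evaluated exactly via a polar-coordinate integral.

No multiple-testing correction is applied across frequencies or channel
pairs: masking is at raw P < alpha per value, which inflates the family
of significant values in the way any per-value rule does. This is a
deliberate, documented property of the pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .gpdc import FrequencyGrid, GPDCSpectrum, compute_gpdc, spectral_transfer
from .mvar import MVARFitError, MVARModel, check_stability, fit_mvar

logger = logging.getLogger(__name__)

SURROGATE = "surrogate"
ASYMPTOTIC = "asymptotic"


class WindowSignificanceError(RuntimeError):
    """Raised when a window's significance computation must be aborted."""


@dataclass
class SignificanceResult:
    """P-values and the P < alpha mask for one window's GPDC array."""

    p_values: np.ndarray  # (D, D, F)
    alpha: float
    method: str
    n_surrogates: int = 0
    n_failed_surrogates: int = 0

    @property
    def mask(self) -> np.ndarray:
        """True where p < alpha (strict: p exactly equal to alpha is not significant)."""
        return self.p_values < self.alpha


def _fit_and_gpdc(block: np.ndarray, order: int, fs: float, grid: FrequencyGrid,
                  window_index: int = 0) -> tuple[MVARModel, GPDCSpectrum]:
    model = fit_mvar(block, order, fs, window_index=window_index)
    return model, compute_gpdc(model, grid)


def surrogate_significance(
    block: np.ndarray,
    order: int,
    fs: float,
    grid: FrequencyGrid,
    alpha: float = 0.05,
    n_surrogates: int = 99,
    rng: np.random.Generator | int | None = None,
    window_index: int = 0,
    observed: GPDCSpectrum | None = None,
) -> tuple[GPDCSpectrum, SignificanceResult]:
    """Circular-shift surrogate test for one window.

    Returns the observed GPDC spectrum and its significance result.
    Identical seeds give bit-identical p-values. Aborts the window
    (:class:`WindowSignificanceError`) if more than 20% of surrogate
    fits fail.
    """
    if n_surrogates < 19:
        raise ValueError("need at least 19 surrogates for P < 0.05 resolution")
    rng = np.random.default_rng(rng)
    block = np.asarray(block, dtype=float)
    n = block.shape[0]
    if observed is None:
        _, observed = _fit_and_gpdc(block, order, fs, grid, window_index)
    obs = observed.values
    ge_count = np.zeros_like(obs, dtype=np.int64)
    max_fail = int(0.2 * n_surrogates)
    failed = 0
    if n <= 2 * order:
        raise WindowSignificanceError("window too short for circular-shift surrogates")
    for _ in range(n_surrogates):
        shifts = rng.integers(order, n - order, size=block.shape[1], endpoint=True)
        surr = np.empty_like(block)
        for c in range(block.shape[1]):
            surr[:, c] = np.roll(block[:, c], int(shifts[c]))
        try:
            _, null_spec = _fit_and_gpdc(surr, order, fs, grid, window_index)
        except MVARFitError:
            failed += 1
            if failed > max_fail:
                raise WindowSignificanceError(
                    f"window {window_index}: {failed}/{n_surrogates} surrogate fits failed"
                )
            continue
        ge_count += null_spec.values >= obs
    n_ok = n_surrogates - failed
    p = (1.0 + ge_count) / (1.0 + n_ok)
    return observed, SignificanceResult(
        p_values=p, alpha=alpha, method=SURROGATE,
        n_surrogates=n_surrogates, n_failed_surrogates=failed,
    )


def _chi2_mixture_sf(q: np.ndarray, lam1: np.ndarray, lam2: np.ndarray,
                     n_theta: int = 96) -> np.ndarray:
    """Exact survival function of lam1*Z1^2 + lam2*Z2^2 (Z_i iid standard normal).

    Uses P(sum > q) = (1/2pi) int_0^{2pi} exp(-q / (2 w(theta))) dtheta with
    w(theta) = lam1 cos^2 + lam2 sin^2; the integrand is smooth and periodic
    so the trapezoid rule converges spectrally.
    """
    theta = np.linspace(0.0, np.pi / 2, n_theta)  # quarter period by symmetry
    c2, s2 = np.cos(theta) ** 2, np.sin(theta) ** 2
    w = lam1[..., None] * c2 + lam2[..., None] * s2
    tiny = np.finfo(float).tiny
    expo = np.where(w > 0, -q[..., None] / np.maximum(2.0 * w, tiny), -np.inf)
    expo = np.where(q[..., None] == 0.0, 0.0, expo)
    vals = np.exp(expo)
    return np.trapezoid(vals, theta, axis=-1) / (np.pi / 2)


def asymptotic_significance(
    model: MVARModel,
    grid: FrequencyGrid,
    alpha: float = 0.05,
) -> SignificanceResult:
    """Asymptotic per-value p-values under the null of no direct coupling.

    Requires a stable fitted model with the inverse Gram matrix attached
    (``fit_mvar`` keeps it); refuses unstable models — use the surrogate
    backend for those. Diagonal entries get p = 1 (self-influence is not a
    tested hypothesis). A structural zero (Abar_ij identically 0) gives
    p = 1 exactly.
    """
    stable, radius = check_stability(model)
    if not stable:
        raise ValueError(
            f"model unstable (spectral radius {radius:.3f}); "
            "use the surrogate significance backend"
        )
    if model.xtx_inv is None or model.n_eff <= 0:
        raise ValueError("model lacks fit metadata (xtx_inv); refit with fit_mvar")
    p_lags, D, F = model.order, model.dim, grid.n_freqs
    A_bar = spectral_transfer(model, grid)
    q_obs = A_bar.real**2 + A_bar.imag**2  # (D, D, F)
    omega = 2.0 * np.pi * grid.freqs / model.fs
    C = np.cos(np.outer(omega, np.arange(1, p_lags + 1)))  # (F, p)
    S = np.sin(np.outer(omega, np.arange(1, p_lags + 1)))
    sigma2 = model.sigma2
    p_values = np.ones((D, D, F))
    for j in range(D):
        sel = j + D * np.arange(p_lags)
        Vj = model.xtx_inv[np.ix_(sel, sel)]  # (p, p); covariance factor per lag poly
        a = np.einsum("fp,pq,fq->f", C, Vj, C)
        b = np.einsum("fp,pq,fq->f", S, Vj, S)
        c = np.einsum("fp,pq,fq->f", C, Vj, S)
        half_tr = 0.5 * (a + b)
        disc = np.sqrt(np.maximum(0.25 * (a - b) ** 2 + c**2, 0.0))
        lam1 = np.maximum(half_tr + disc, 0.0)  # (F,)
        lam2 = np.maximum(half_tr - disc, 0.0)
        for i in range(D):
            if i == j:
                continue
            p_values[i, j] = _chi2_mixture_sf(
                q_obs[i, j], sigma2[i] * lam1, sigma2[i] * lam2
            )
    return SignificanceResult(p_values=p_values, alpha=alpha, method=ASYMPTOTIC)


def window_significance(
    block: np.ndarray,
    order: int,
    fs: float,
    grid: FrequencyGrid,
    method: str = SURROGATE,
    alpha: float = 0.05,
    n_surrogates: int = 99,
    rng: np.random.Generator | int | None = None,
    window_index: int = 0,
) -> tuple[MVARModel, GPDCSpectrum, SignificanceResult]:
    """Fit + GPDC + significance for one window with the configured backend."""
    model, spec = _fit_and_gpdc(block, order, fs, grid, window_index)
    if method == SURROGATE:
        _, sig = surrogate_significance(
            block, order, fs, grid, alpha=alpha, n_surrogates=n_surrogates,
            rng=rng, window_index=window_index, observed=spec,
        )
    elif method == ASYMPTOTIC:
        sig = asymptotic_significance(model, grid, alpha=alpha)
    else:
        raise ValueError(f"unknown significance method {method!r}")
    return model, spec, sig
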