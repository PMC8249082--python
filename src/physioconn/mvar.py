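"""Multivariate autoregressive (MVAR) model fitting and diagnostics.

Each D-channel analysis window is modeled as

    x(t) = sum_{r=1..p} A_r x(t-r) + e(t),   e ~ N(0, Sigma)

with the coefficient stack ``A_1..A_p`` estimated by multivariate
ordinary least squares on the lagged design matrix. Entry ``A_r[i, j]``
is the influence of channel j at lag r on channel i — the same
from-column/to-row convention used throughout the package.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as _la

logger = logging.getLogger(__name__)


class MVARFitError(RuntimeError):
    """Raised when a window's regressor Gram matrix is singular (e.g. a constant channel)."""


@dataclass
class MVARModel:
    """Fitted MVAR model for one analysis window.

    Attributes
    ----------
    coeffs : ndarray of shape (p, D, D)
        Lag coefficient matrices ``A_1..A_p``; ``coeffs[r-1, i, j]`` is the
        lag-r influence of channel j on channel i.
    noise_cov : ndarray of shape (D, D)
        Residual covariance with the small-sample divisor ``n_eff - p*D``;
        its diagonal holds the innovation variances ``sigma_k^2``.
    xtx_inv : ndarray of shape (p*D, p*D), optional
        Inverse regressor Gram matrix (lag-major column order), kept for
        asymptotic significance testing.
    """

    coeffs: np.ndarray
    noise_cov: np.ndarray
    order: int
    dim: int
    fs: float
    window_index: int = 0
    n_samples: int = 0
    n_eff: int = 0
    xtx_inv: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        self.noise_cov = np.asarray(self.noise_cov, dtype=float)
        if self.coeffs.shape != (self.order, self.dim, self.dim):
            raise ValueError(
                f"coeffs shape {self.coeffs.shape} != (p={self.order}, D={self.dim}, D)"
            )
        if self.noise_cov.shape != (self.dim, self.dim):
            raise ValueError("noise_cov must be D x D")
        if np.any(np.diag(self.noise_cov) <= 0):
            raise ValueError("noise covariance diagonal must be strictly positive")

    @property
    def sigma2(self) -> np.ndarray:
        """Innovation variances sigma_k^2 (diagonal of the residual covariance)."""
        return np.diag(self.noise_cov)

    def companion(self) -> np.ndarray:
        """pD x pD companion matrix whose eigenvalues govern stability."""
        p, D = self.order, self.dim
        C = np.zeros((p * D, p * D))
        C[:D] = np.concatenate([self.coeffs[r] for r in range(p)], axis=1)
        if p > 1:
            C[D:, : (p - 1) * D] = np.eye((p - 1) * D)
        return C


def lagged_design(block: np.ndarray, order: int) -> tuple[np.ndarray, np.ndarray]:
    """Build the OLS design: rows ``[x(t-1), ..., x(t-p)]`` (lag-major) and targets x(t)."""
    x = np.asarray(block, dtype=float)
    n, D = x.shape
    p = order
    Z = np.empty((n - p, p * D))
    for r in range(1, p + 1):
        Z[:, (r - 1) * D : r * D] = x[p - r : n - r]
    return Z, x[p:]


def fit_mvar(
    block: np.ndarray,
    order: int,
    fs: float,
    window_index: int = 0,
    demean: bool = True,
) -> MVARModel:
    """Fit an MVAR(p) model to one window by multivariate OLS.

    Per-channel means are removed first (``demean``). Deterministic for a
    fixed block. Raises :class:`MVARFitError` when the lagged regressor
    Gram matrix is singular, e.g. for a constant channel; callers should
    exclude such windows downstream.
    """
    x = np.asarray(block, dtype=float)
    if x.ndim != 2:
        raise ValueError("block must be 2-D (samples x channels)")
    n, D = x.shape
    p = int(order)
    if p < 1 or n <= p:
        raise ValueError(f"need more than p={p} samples, got {n}")
    if n <= 100 * p * D:
        warnings.warn(
            f"window of {n} samples is below the recommended 100x data-to-parameter "
            f"margin for p={p}, D={D}",
            stacklevel=2,
        )
    if demean:
        x = x - x.mean(axis=0)
    Z, Y = lagged_design(x, p)
    G = Z.T @ Z
    try:
        cho = _la.cho_factor(G, lower=True)
    except _la.LinAlgError as exc:
        raise MVARFitError(
            f"singular regressor Gram matrix in window {window_index} "
            f"(constant or collinear channel?)"
        ) from exc
    B = _la.cho_solve(cho, Z.T @ Y)  # (pD, D)
    resid = Y - Z @ B
    n_eff = n - p
    dof = n_eff - p * D
    if dof <= 0:
        raise MVARFitError(f"window {window_index}: not enough samples for p={p}, D={D}")
    noise_cov = (resid.T @ resid) / dof
    if np.any(np.diag(noise_cov) <= 0):
        raise MVARFitError(f"window {window_index}: degenerate residual variance")
    coeffs = np.stack([B[(r - 1) * D : r * D].T for r in range(1, p + 1)])
    xtx_inv = _la.cho_solve(cho, np.eye(p * D))
    return MVARModel(
        coeffs=coeffs,
        noise_cov=noise_cov,
        order=p,
        dim=D,
        fs=float(fs),
        window_index=window_index,
        n_samples=n,
        n_eff=n_eff,
        xtx_inv=xtx_inv,
    )


def check_stability(model: MVARModel) -> tuple[bool, float]:
    """Companion-matrix stability check: ``(stable, spectral_radius)``.

    The model is stable iff every companion eigenvalue has modulus < 1.
    """
    if not np.any(model.coeffs):
        return True, 0.0
    radius = float(np.max(np.abs(np.linalg.eigvals(model.companion()))))
    return radius < 1.0, radius


def residuals(model: MVARModel, block: np.ndarray, demean: bool = True) -> np.ndarray:
    """One-step-ahead residuals of a fitted model on a block."""
    x = np.asarray(block, dtype=float)
    if demean:
        x = x - x.mean(axis=0)
    Z, Y = lagged_design(x, model.order)
    B = np.concatenate([model.coeffs[r].T for r in range(model.order)], axis=0)
    return Y - Z @ B


def information_criteria(block: np.ndarray, orders, fs: float) -> "pd.DataFrame":
    """AIC/BIC per candidate order (diagnostic only; the pipeline does not auto-select)."""
    import pandas as pd

    rows = []
    for p in orders:
        try:
            m = fit_mvar(block, p, fs)
        except MVARFitError:
            rows.append({"order": p, "aic": np.nan, "bic": np.nan, "failed": True})
            continue
        n_eff = m.n_eff
        _, logdet = np.linalg.slogdet(m.noise_cov)
        k = p * m.dim * m.dim
        rows.append(
            {
                "order": p,
                "aic": logdet + 2.0 * k / n_eff,
                "bic": logdet + np.log(n_eff) * k / n_eff,
                "failed": False,
            }
        )
    return pd.DataFrame(rows)


def model_to_table(model: MVARModel) -> "pd.DataFrame":
    """Columnar dump: window_index, lag r, to-channel i, from-channel j, coefficient."""
    import pandas as pd

    p, D = model.order, model.dim
    r, i, j = np.meshgrid(np.arange(1, p + 1), np.arange(D), np.arange(D), indexing="ij")
    return pd.DataFrame(
        {
            "window_index": model.window_index,
            "lag": r.ravel(),
            "to_channel": i.ravel(),
            "from_channel": j.ravel(),
            "coefficient": model.coeffs.ravel(),
        }
    )
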