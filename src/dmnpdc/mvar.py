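"""Multivariate autoregressive (MVAR) model fitting and order selection.

An MVAR(p) model expresses the channel vector x_t as a lagged linear
combination of all channels plus innovation noise:

    x_t = sum_{r=1..p} A_r x_{t-r} + e_t,   e_t ~ N(0, Sigma)

with ``A_r[i, j]`` the influence of channel j at lag r on channel i.
Estimation is stacked ordinary least squares; the model order is chosen by
the Akaike information criterion. Stability (stationarity) is equivalent to
the companion matrix having spectral radius < 1.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "MvarModel",
    "fit_mvar",
    "aic",
    "select_order",
    "check_stability",
]


@dataclass
class MvarModel:
    """Fitted or ground-truth MVAR model.

    Parameters
    ----------
    coefs
        Array of shape ``(p, n, n)``; ``coefs[r-1][i, j]`` is the influence
        of channel j at lag r on channel i.
    sigma
        Innovation covariance, ``(n, n)``, symmetric positive semi-definite.
    fs
        Sampling rate of the modelled series in Hz.
    n_obs
        Number of regression rows (effective observations) used in the fit;
        for ground-truth models this may be 0.
    """

    coefs: np.ndarray
    sigma: np.ndarray
    fs: float
    n_obs: int = 0

    def __post_init__(self) -> None:
        self.coefs = np.asarray(self.coefs, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.coefs.ndim != 3 or self.coefs.shape[1] != self.coefs.shape[2]:
            raise ValueError("coefs must have shape (p, n, n)")
        n = self.coefs.shape[1]
        if self.sigma.shape != (n, n):
            raise ValueError("sigma shape inconsistent with coefs")

    @property
    def order(self) -> int:
        return self.coefs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.coefs.shape[1]

    def companion(self) -> np.ndarray:
        """(n*p, n*p) companion matrix of the MVAR(1) reformulation."""
        p, n = self.order, self.n_channels
        comp = np.zeros((n * p, n * p))
        comp[:n, :] = np.concatenate(list(self.coefs), axis=1)
        if p > 1:
            comp[n:, :-n] = np.eye(n * (p - 1))
        return comp

    def spectral_radius(self) -> float:
        return float(np.max(np.abs(np.linalg.eigvals(self.companion()))))

    def to_json(self) -> str:
        return json.dumps(
            {
                "order": self.order,
                "fs": self.fs,
                "n_obs": self.n_obs,
                "coefs": self.coefs.tolist(),
                "sigma": self.sigma.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "MvarModel":
        d = json.loads(text)
        return cls(
            coefs=np.array(d["coefs"]),
            sigma=np.array(d["sigma"]),
            fs=d["fs"],
            n_obs=d["n_obs"],
        )


def _regression_blocks(
    epochs: np.ndarray, p: int
) -> tuple[np.ndarray, np.ndarray]:
    """Stack the lagged regression for one or more epochs.

    ``epochs`` is ``(n, T)`` or ``(E, n, T)``. Rows never straddle an epoch
    boundary. Returns (X, Y) with X ``(rows, n*p)`` ordered lag-major
    (all channels at lag 1, then lag 2, ...), Y ``(rows, n)``.
    """
    if epochs.ndim == 2:
        epochs = epochs[None]
    E, n, T = epochs.shape
    if p <= 0:
        raise ValueError("order p must be positive")
    if T <= n * p + 1:
        raise ValueError(
            f"epoch too short: need more than n*p + 1 = {n * p + 1} samples, got {T}"
        )
    xs, ys = [], []
    for e in range(E):
        data = epochs[e]
        Y = data[:, p:].T  # (T-p, n)
        X = np.concatenate(
            [data[:, p - r : T - r].T for r in range(1, p + 1)], axis=1
        )
        xs.append(X)
        ys.append(Y)
    return np.concatenate(xs), np.concatenate(ys)


def fit_mvar(epochs: np.ndarray, p: int, fs: float = 1.0) -> MvarModel:
    """Fit an MVAR(p) by stacked OLS on one epoch ``(n, T)`` or a stack
    ``(E, n, T)`` of epochs (rows pooled, never crossing epoch boundaries).

    The input is assumed zero-mean per channel. ``sigma`` is the residual
    covariance with denominator ``rows - n*p`` (observations minus
    parameters per equation).
    """
    epochs = np.asarray(epochs, dtype=float)
    n = epochs.shape[-2]
    X, Y = _regression_blocks(epochs, p)
    B, _, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
    if rank < n * p:
        raise ValueError(
            "rank-deficient regressor matrix (constant or collinear channel)"
        )
    resid = Y - X @ B
    rows = X.shape[0]
    df = rows - n * p
    if df <= 0:
        raise ValueError("not enough observations for the requested order")
    sigma = resid.T @ resid / df
    # B is (n*p, n), lag-major: B[(r-1)*n + j, i] = A_r[i, j]
    coefs = np.transpose(B.reshape(p, n, n), (0, 2, 1))
    return MvarModel(coefs=coefs, sigma=sigma, fs=fs, n_obs=rows)


def aic(model: MvarModel) -> float:
    """Akaike information criterion: N ln det(Sigma) + 2 p n^2.

    N is the number of effective observations used in the fit. Smaller is
    better. A singular Sigma is regularised by ``eps * I`` with
    ``eps = 1e-12 * trace scale`` and a warning is emitted.
    """
    n = model.n_channels
    sign, logdet = np.linalg.slogdet(model.sigma)
    if sign <= 0 or not np.isfinite(logdet):
        eps = 1e-12 * max(np.trace(model.sigma) / n, np.finfo(float).tiny)
        warnings.warn(
            "singular innovation covariance; AIC computed on sigma + eps*I",
            RuntimeWarning,
            stacklevel=2,
        )
        sign, logdet = np.linalg.slogdet(model.sigma + eps * np.eye(n))
    return float(model.n_obs * logdet + 2 * model.order * n * n)


def select_order(
    epochs: np.ndarray,
    p_min: int = 1,
    p_max: int = 12,
    fs: float = 1.0,
) -> int:
    """AIC-minimising order over ``p_min..p_max``; ties go to the smaller p."""
    if p_min < 1 or p_max < p_min:
        raise ValueError("invalid order range")
    best_p, best_aic = None, np.inf
    for p in range(p_min, p_max + 1):
        try:
            model = fit_mvar(epochs, p, fs=fs)
        except ValueError:
            break  # larger p is even less feasible
        a = aic(model)
        if a < best_aic:  # strict: ties keep the smaller p
            best_p, best_aic = p, a
    if best_p is None:
        raise ValueError("no feasible order in the requested range")
    return best_p


def check_stability(model: MvarModel, tol: float = 1e-6) -> bool:
    """True iff the companion spectral radius is below ``1 - tol``."""
    return model.spectral_radius() < 1.0 - tol
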