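"""Partial directed coherence (PDC) from MVAR models.

PDC is a frequency-domain formulation of Granger causality. With the
frequency-transformed coefficient matrix

    Abar(f) = I - sum_{r=1..p} A_r exp(-i 2 pi f r / fs)

the (column-normalised) PDC from source channel j to sink channel i is

    pi_ij(f) = |Abar_ij(f)| / sqrt( sum_k |Abar_kj(f)|^2 )

so that sum_i pi_ij(f)^2 = 1 for every source column j at every frequency.
Band-averaged, epoch-aggregated PDC forms the per-subject connectivity
tensor (channels x channels x bands, diagonal zeroed for reporting).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .mvar import MvarModel, check_stability, fit_mvar, select_order

__all__ = [
    "Band",
    "BandScheme",
    "DEFAULT_BANDS",
    "PdcSpectrum",
    "ConnectivityTensor",
    "a_bar",
    "pdc_spectrum",
    "band_average",
    "subject_connectivity",
]


@dataclass(frozen=True)
class Band:
    """Named frequency interval. Membership is half-open ``[lo, hi)`` unless
    ``closed`` (used for the last band so 30 Hz belongs to high beta)."""

    name: str
    lo: float
    hi: float
    closed: bool = False

    def mask(self, freqs: np.ndarray) -> np.ndarray:
        upper = freqs <= self.hi if self.closed else freqs < self.hi
        return (freqs >= self.lo) & upper


@dataclass(frozen=True)
class BandScheme:
    bands: tuple[Band, ...]

    def __post_init__(self) -> None:
        prev_hi = 0.0
        for b in self.bands:
            if not (0 < b.lo < b.hi):
                raise ValueError(f"band {b.name}: need 0 < lo < hi")
            if b.lo < prev_hi:
                raise ValueError("bands must be disjoint and ordered")
            prev_hi = b.hi

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(b.name for b in self.bands)

    def __len__(self) -> int:
        return len(self.bands)

    def __getitem__(self, key: int | str) -> Band:
        if isinstance(key, str):
            for b in self.bands:
                if b.name == key:
                    return b
            raise KeyError(key)
        return self.bands[key]


#: Canonical five-band scheme. The reported clinical edges (delta 1-3, alpha
#: 8-12, low beta 13-21) leave 1-Hz gaps; half-open intervals close them.
DEFAULT_BANDS = BandScheme(
    (
        Band("delta", 1.0, 4.0),
        Band("theta", 4.0, 8.0),
        Band("alpha", 8.0, 13.0),
        Band("low_beta", 13.0, 22.0),
        Band("high_beta", 22.0, 30.0, closed=True),
    )
)


@dataclass
class PdcSpectrum:
    """Frequency-resolved PDC: ``pi[i, j, f]`` is the influence of source j
    on sink i at ``freqs[f]``."""

    freqs: np.ndarray
    pi: np.ndarray
    fs: float
    squared: bool = False


@dataclass
class ConnectivityTensor:
    """Band-averaged, epoch-aggregated PDC for one subject.

    ``values`` is ``(n, n, n_bands)`` with the diagonal zeroed (a channel's
    self-influence is not reported).
    """

    values: np.ndarray
    band_names: tuple[str, ...]
    subject_id: str = ""
    n_epochs: int = 0
    labels: tuple[str, ...] = field(default=())

    def band(self, name: str) -> np.ndarray:
        return self.values[:, :, self.band_names.index(name)]

    def mean_offdiag(self, band: str | None = None) -> float:
        """Mean off-diagonal PDC, over one band or over all bands."""
        vals = self.values if band is None else self.band(band)[..., None]
        n = vals.shape[0]
        mask = ~np.eye(n, dtype=bool)
        return float(vals[mask].mean())


def default_freq_grid(fs: float, step: float = 0.5) -> np.ndarray:
    """Frequency grid from 0 to Nyquist inclusive."""
    return np.arange(0.0, fs / 2 + step / 2, step)


def a_bar(model: MvarModel, f: float) -> np.ndarray:
    """Frequency-transformed coefficient matrix at a single frequency."""
    return _a_bar_grid(model, np.atleast_1d(float(f)))[0]


def _a_bar_grid(model: MvarModel, freqs: np.ndarray) -> np.ndarray:
    p, n = model.order, model.n_channels
    lags = np.arange(1, p + 1)
    # phases: (F, p)
    phases = np.exp(-2j * np.pi * np.outer(freqs, lags) / model.fs)
    abar = np.eye(n, dtype=complex) - np.einsum(
        "fp,pij->fij", phases, model.coefs
    )
    return abar


def pdc_spectrum(
    model: MvarModel,
    freqs: np.ndarray | None = None,
    squared: bool = False,
    check: bool = True,
) -> PdcSpectrum:
    """Column-normalised PDC of a (stable) MVAR model over a frequency grid.

    ``squared=True`` returns |pi|^2 (the normalisation identity then reads
    sum_i pi_ij = 1).
    """
    if check and not check_stability(model):
        raise ValueError("PDC requires a stable MVAR model")
    if freqs is None:
        freqs = default_freq_grid(model.fs)
    freqs = np.asarray(freqs, dtype=float)
    abar = _a_bar_grid(model, freqs)  # (F, n, n)
    mag = np.abs(abar)
    colnorm = np.sqrt(np.sum(mag**2, axis=1, keepdims=True))  # over sinks
    if np.any(colnorm == 0.0):
        raise ValueError("zero column norm in Abar(f); degenerate model")
    pi = mag / colnorm
    if squared:
        pi = pi**2
    return PdcSpectrum(
        freqs=freqs, pi=np.moveaxis(pi, 0, -1), fs=model.fs, squared=squared
    )


def band_average(spec: PdcSpectrum, bands: BandScheme = DEFAULT_BANDS) -> np.ndarray:
    """Arithmetic mean of the PDC spectrum over each band's grid frequencies.

    Returns ``(n, n, n_bands)``.
    """
    out = []
    for b in bands.bands:
        mask = b.mask(spec.freqs)
        if not mask.any():
            raise ValueError(f"band {b.name} contains no grid frequency")
        out.append(spec.pi[:, :, mask].mean(axis=-1))
    return np.stack(out, axis=-1)


def subject_connectivity(
    epochs,
    order_policy: int | str = "aic",
    aggregate: str = "pooled",
    bands: BandScheme = DEFAULT_BANDS,
    squared: bool = False,
    subject_id: str = "",
    p_range: tuple[int, int] = (1, 12),
) -> ConnectivityTensor:
    """Per-subject band-averaged PDC tensor from an epoch set.

    Parameters
    ----------
    epochs
        ``EpochSet`` (from :mod:`dmnpdc.preprocessing`) or an array
        ``(E, n, T)``.
    order_policy
        Fixed integer order, or ``"aic"`` to select the order once per
        subject on the pooled epochs and hold it fixed.
    aggregate
        ``"pooled"`` (default): one MVAR fit with regression rows stacked
        across epochs, then one PDC. ``"per_epoch"``: fit each epoch,
        average the band-averaged PDC across stable epoch fits (unstable
        fits are skipped with a warning).
    """
    data = np.asarray(getattr(epochs, "epochs", epochs), dtype=float)
    fs = float(getattr(epochs, "fs", 1.0))
    labels = tuple(getattr(epochs, "labels", ()) or ())
    if data.ndim == 2:
        data = data[None]
    if data.shape[0] < 1:
        raise ValueError("need at least one epoch")
    data = data - data.mean(axis=-1, keepdims=True)  # zero-mean per channel

    if order_policy == "aic":
        p = select_order(data, *p_range, fs=fs)
    else:
        p = int(order_policy)

    if aggregate == "pooled":
        model = fit_mvar(data, p, fs=fs)
        radius = model.spectral_radius()
        if radius >= 1.2:
            raise ValueError(
                f"pooled MVAR fit grossly unstable (radius {radius:.3f})"
            )
        if radius >= 1.0 - 1e-6:
            # band-pass filtered data can push fitted poles slightly across
            # the unit circle; PDC is an algebraic functional of the
            # coefficients and remains well defined
            warnings.warn(
                f"pooled MVAR fit mildly unstable (radius {radius:.4f}); "
                "PDC computed from the fitted coefficients",
                RuntimeWarning,
                stacklevel=2,
            )
        values = band_average(
            pdc_spectrum(model, squared=squared, check=False), bands
        )
        n_used = data.shape[0]
    elif aggregate == "per_epoch":
        mats = []
        for e in range(data.shape[0]):
            model = fit_mvar(data[e], p, fs=fs)
            if not check_stability(model):
                warnings.warn(
                    f"epoch {e}: unstable MVAR fit skipped", RuntimeWarning,
                    stacklevel=2,
                )
                continue
            mats.append(
                band_average(pdc_spectrum(model, squared=squared), bands)
            )
        if not mats:
            raise ValueError("all epoch fits unstable")
        values = np.mean(mats, axis=0)
        n_used = len(mats)
    else:
        raise ValueError(f"unknown aggregate mode: {aggregate!r}")

    n = values.shape[0]
    values = values.copy()
    values[np.arange(n), np.arange(n), :] = 0.0  # reporting convention
    return ConnectivityTensor(
        values=values,
        band_names=bands.names,
        subject_id=subject_id,
        n_epochs=n_used,
        labels=labels,
    )
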