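"""Absolute spectral band power from epoched data.

Welch-averaged periodograms (Hann window, density normalisation) integrated
over the four clinical bands: delta, theta, alpha and combined beta
(13-30 Hz, merging low and high beta).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal

from .pdc import Band

__all__ = ["POWER_BANDS", "welch_psd", "absolute_band_power"]

#: Band-power scheme: beta is reported as a single 13-30 Hz band.
POWER_BANDS = (
    Band("delta", 1.0, 4.0),
    Band("theta", 4.0, 8.0),
    Band("alpha", 8.0, 13.0),
    Band("beta", 13.0, 30.0, closed=True),
)


def welch_psd(
    epochs,
    segment_s: float = 2.0,
    overlap: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel Welch power spectral density, averaged across epochs.

    Returns ``(freqs, psd)`` with ``psd`` of shape ``(n_channels, n_freqs)``
    in signal-units^2/Hz, normalised so that the integral over [0, fs/2]
    equals the signal variance (Parseval).
    """
    data = np.asarray(getattr(epochs, "epochs", epochs), dtype=float)
    fs = float(getattr(epochs, "fs", 1.0))
    if data.ndim == 2:
        data = data[None]
    nperseg = int(round(segment_s * fs))
    if nperseg > data.shape[-1]:
        raise ValueError("Welch segment longer than the epoch")
    freqs, psd = signal.welch(
        data,
        fs=fs,
        window="hann",
        nperseg=nperseg,
        noverlap=int(round(nperseg * overlap)),
        detrend="constant",
        scaling="density",
        axis=-1,
    )
    return freqs, psd.mean(axis=0)  # average across epochs


def absolute_band_power(
    freqs: np.ndarray,
    psd: np.ndarray,
    bands: tuple[Band, ...] = POWER_BANDS,
    labels: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Trapezoidal integral of the PSD over each band.

    Returns a long-format table with columns ``channel``, ``band``,
    ``power`` (signal-units^2).
    """
    psd = np.atleast_2d(psd)
    rows = []
    for b in bands:
        mask = (freqs >= b.lo) & (freqs <= b.hi)
        if mask.sum() < 2:
            raise ValueError(f"band {b.name} too narrow for the PSD grid")
        power = np.trapezoid(psd[:, mask], freqs[mask], axis=1)
        for ch in range(psd.shape[0]):
            rows.append(
                {
                    "channel": labels[ch] if labels else str(ch),
                    "band": b.name,
                    "power": float(power[ch]),
                }
            )
    return pd.DataFrame(rows)
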