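"""Epoch preprocessing: band-pass / notch filtering, middle-window
trimming, and per-epoch temporal mean subtraction.

The resting-state recordings the pipeline targets were band-pass filtered
0.5-55 Hz with a 60 Hz notch, cut into 30 s epochs of which only the
middle 20 s (5-25 s) is analyzed — discarding the transients around the
instruction to open or close the eyes — and demeaned per epoch in lieu of
a true baseline.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .recording import EpochedRecording

__all__ = [
    "band_pass",
    "notch",
    "trim_middle",
    "subtract_epoch_mean",
    "preprocess_recording",
]


def band_pass(
    data: np.ndarray, sfreq: float, low: float = 0.5, high: float = 55.0,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the last axis."""
    if not 0 < low < high < sfreq / 2:
        raise ValueError("need 0 < low < high < Nyquist")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=sfreq, output="sos")
    return sps.sosfiltfilt(sos, data, axis=-1)


def notch(data: np.ndarray, sfreq: float, freq: float = 60.0, q: float = 30.0
          ) -> np.ndarray:
    """Zero-phase IIR notch (power-line removal) along the last axis."""
    b, a = sps.iirnotch(freq, q, fs=sfreq)
    return sps.filtfilt(b, a, data, axis=-1)


def trim_middle(
    data: np.ndarray, sfreq: float, start: float = 5.0, stop: float = 25.0
) -> np.ndarray:
    """Keep only the [start, stop) window of each epoch, in seconds."""
    n = data.shape[-1]
    i0, i1 = int(round(start * sfreq)), int(round(stop * sfreq))
    if i1 > n:
        raise ValueError(
            f"epoch of {n} samples too short to trim to [{start}, {stop}) s "
            f"at {sfreq} Hz (needs {i1})"
        )
    return data[..., i0:i1]


def subtract_epoch_mean(data: np.ndarray) -> np.ndarray:
    """Remove each epoch/channel's temporal mean."""
    return data - data.mean(axis=-1, keepdims=True)


def preprocess_recording(
    rec: EpochedRecording,
    low: float = 0.5,
    high: float = 55.0,
    notch_freq: float | None = 60.0,
    trim: tuple[float, float] | None = (5.0, 25.0),
) -> EpochedRecording:
    """Filter, optionally notch, trim and demean every epoch.

    ``trim=None`` skips the middle-window cut (for epochs already at
    their analysis length); ``notch_freq=None`` skips the notch.  The
    notch is applied only when the line frequency lies inside the
    band-pass (otherwise the band-pass already removes it).
    """
    data = band_pass(rec.data, rec.sfreq, low, high)
    if notch_freq is not None and low < notch_freq < high:
        data = notch(data, rec.sfreq, notch_freq)
    if trim is not None:
        data = trim_middle(data, rec.sfreq, *trim)
    data = subtract_epoch_mean(data)
    return EpochedRecording(
        data=data,
        sfreq=rec.sfreq,
        condition_labels=rec.condition_labels,
        subject=rec.subject,
        channel_names=rec.channel_names,
    )
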