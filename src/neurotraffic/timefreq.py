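"""Complex-Morlet wavelet scalograms and scale/pseudo-frequency mapping.

The analysis views the EEG through a continuous wavelet transform with a
complex Morlet mother wavelet

    psi(t) = (pi * fb)**(-1/2) * exp(2j*pi*fc*t) * exp(-t**2 / fb)

where ``fc`` is the center frequency (Hz) and ``fb`` the Gaussian envelope
bandwidth parameter (s^2).  At scale ``a`` and sampling interval ``dt`` the
wavelet responds to oscillations near the pseudo-frequency

    f_pseudo = fc / (a * dt)

Signal power is the squared modulus of the complex wavelet coefficients;
only power is used downstream (phase is discarded).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pywt

__all__ = [
    "WaveletSpec",
    "Scalogram",
    "pseudo_frequency",
    "scales_for_frequencies",
    "morlet_scalogram",
]

#: Number of Gaussian standard deviations defining the wavelet's effective
#: half-support (used for the minimum-length check and the cone of influence).
_SUPPORT_SIGMAS = 4.0


@dataclass(frozen=True)
class WaveletSpec:
    """Parameters of the complex Morlet analysis.

    Parameters
    ----------
    center_frequency : float
        Mother-wavelet center frequency ``fc`` in Hz.  Default 1 Hz.
    bandwidth : float
        Gaussian envelope bandwidth parameter ``fb`` in s^2 at scale 1.
        Default 2.0, a narrow envelope that maximizes temporal precision
        while retaining at least two full cycles of the carrier.
    analysis_frequencies : tuple of float
        Pseudo-frequencies (Hz) at which the scalogram is evaluated.
        Default 5-30 Hz in steps of 5 Hz.
    """

    center_frequency: float = 1.0
    bandwidth: float = 2.0
    analysis_frequencies: tuple[float, ...] = (5.0, 10.0, 15.0, 20.0, 25.0, 30.0)

    def __post_init__(self) -> None:
        if self.center_frequency <= 0:
            raise ValueError("center_frequency must be > 0")
        if self.bandwidth <= 0:
            raise ValueError("bandwidth must be > 0")
        freqs = tuple(float(f) for f in self.analysis_frequencies)
        if len(freqs) == 0:
            raise ValueError("analysis_frequencies must be non-empty")
        if any(f <= 0 for f in freqs):
            raise ValueError("analysis_frequencies must be strictly positive")
        if any(b <= a for a, b in zip(freqs, freqs[1:])):
            raise ValueError("analysis_frequencies must be strictly increasing")
        object.__setattr__(self, "analysis_frequencies", freqs)

    @property
    def wavelet_name(self) -> str:
        """PyWavelets name of the matching complex Morlet wavelet."""
        return f"cmor{self.bandwidth:g}-{self.center_frequency:g}"


@dataclass
class Scalogram:
    """Wavelet power of one or more channels across scales and time.

    Attributes
    ----------
    power : ndarray, shape (n_channels, n_scales, n_times)
        Squared modulus of the complex wavelet coefficients; nonnegative.
    scales : ndarray of float
        Wavelet scales ``a`` (dimensionless, in samples of dilation).
    pseudo_frequencies : ndarray of float
        ``fc / (a * dt)`` for each scale, in Hz.
    sample_interval : float
        Digitization interval ``dt`` in seconds.
    coi_halfwidth : ndarray of int
        Per-scale cone-of-influence half-width in samples: coefficients
        within this many samples of either edge are contaminated by the
        zero-padding of the convolution.
    """

    power: np.ndarray
    scales: np.ndarray
    pseudo_frequencies: np.ndarray
    sample_interval: float
    coi_halfwidth: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power, dtype=float)
        if self.power.ndim == 2:
            self.power = self.power[np.newaxis]
        if self.power.ndim != 3:
            raise ValueError("power must be (channels, scales, times)")
        self.scales = np.asarray(self.scales, dtype=float)
        self.pseudo_frequencies = np.asarray(self.pseudo_frequencies, dtype=float)
        if len(self.scales) != len(self.pseudo_frequencies):
            raise ValueError("scales and pseudo_frequencies must align")
        if self.power.shape[1] != len(self.scales):
            raise ValueError("power scale axis does not match scales")
        if self.coi_halfwidth is None:
            self.coi_halfwidth = np.zeros(len(self.scales), dtype=int)

    @property
    def n_channels(self) -> int:
        return self.power.shape[0]

    @property
    def n_times(self) -> int:
        return self.power.shape[2]

    def to_hdf5(self, path, group: str = "scalogram") -> None:
        """Write power and metadata to an HDF5 file, one dataset per channel."""
        import h5py

        with h5py.File(path, "a") as f:
            g = f.require_group(group)
            g.attrs["sample_interval"] = self.sample_interval
            g.create_dataset("scales", data=self.scales)
            g.create_dataset("pseudo_frequencies", data=self.pseudo_frequencies)
            g.create_dataset("coi_halfwidth", data=self.coi_halfwidth)
            ch = g.require_group("channels")
            for c in range(self.n_channels):
                ch.create_dataset(f"ch{c:03d}", data=self.power[c])

    @classmethod
    def from_hdf5(cls, path, group: str = "scalogram") -> "Scalogram":
        import h5py

        with h5py.File(path, "r") as f:
            g = f[group]
            names = sorted(g["channels"])
            power = np.stack([g["channels"][n][()] for n in names])
            return cls(
                power=power,
                scales=g["scales"][()],
                pseudo_frequencies=g["pseudo_frequencies"][()],
                sample_interval=float(g.attrs["sample_interval"]),
                coi_halfwidth=g["coi_halfwidth"][()],
            )


def pseudo_frequency(
    scale: float, sample_interval: float, center_frequency: float = 1.0
) -> float:
    """Pseudo-frequency (Hz) of a wavelet scale: ``fc / (a * dt)``.

    Raises
    ------
    ValueError
        If any argument is not strictly positive.
    """
    if scale <= 0 or sample_interval <= 0 or center_frequency <= 0:
        raise ValueError("scale, sample_interval and center_frequency must be > 0")
    return center_frequency / (scale * sample_interval)


def scales_for_frequencies(
    spec: WaveletSpec, sample_interval: float
) -> np.ndarray:
    """Scales whose pseudo-frequencies equal ``spec.analysis_frequencies``.

    Inverts the pseudo-frequency relation; the result is strictly
    decreasing because the frequencies are strictly increasing.
    """
    if sample_interval <= 0:
        raise ValueError("sample_interval must be > 0")
    freqs = np.asarray(spec.analysis_frequencies, dtype=float)
    return spec.center_frequency / (freqs * sample_interval)


def _coi_halfwidths(scales: np.ndarray, bandwidth: float) -> np.ndarray:
    # Gaussian envelope std at scale a is a*sqrt(fb/2) samples.
    sigma = np.asarray(scales) * math.sqrt(bandwidth / 2.0)
    return np.ceil(_SUPPORT_SIGMAS * sigma).astype(int)


def wavelet_support_samples(scale: float, bandwidth: float) -> int:
    """Effective wavelet support (samples) at a scale: +/- 4 envelope SDs."""
    return int(2 * _coi_halfwidths(np.array([scale]), bandwidth)[0])


def morlet_scalogram(
    signal: np.ndarray,
    sample_interval: float,
    spec: WaveletSpec | None = None,
) -> Scalogram:
    """Complex-Morlet scalogram of one channel (or a channels x times array).

    Power is ``|W(a, t)|**2`` with the same time axis as the input; the
    convolution zero-pads at the edges and the per-scale cone of influence
    is recorded on the result so downstream trough detection can drop
    events contaminated by the padding.

    Raises
    ------
    ValueError
        If the signal is shorter than four times the longest wavelet
        support, contains non-finite values, or ``sample_interval <= 0``.
    """
    if spec is None:
        spec = WaveletSpec()
    if sample_interval <= 0:
        raise ValueError("sample_interval must be > 0")
    x = np.asarray(signal, dtype=float)
    if x.ndim == 1:
        x = x[np.newaxis]
    if x.ndim != 2:
        raise ValueError("signal must be 1-D or (channels, times)")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite values")

    scales = scales_for_frequencies(spec, sample_interval)
    min_len = 4 * wavelet_support_samples(float(scales.max()), spec.bandwidth)
    if x.shape[1] < min_len:
        raise ValueError(
            f"signal length {x.shape[1]} is below the minimum {min_len} samples "
            f"(4 x the longest wavelet support at scale {scales.max():.1f})"
        )

    # precision=16 samples the integrated wavelet finely enough that large
    # scales carry no staircase quantization ripple (which would otherwise
    # contaminate trough detection downstream)
    coefs, _ = pywt.cwt(
        x, scales, spec.wavelet_name, sampling_period=sample_interval,
        method="fft", precision=16,
    )
    # pywt returns (n_scales, n_channels, n_times); reorder to channel-major.
    power = np.abs(np.moveaxis(coefs, 0, 1)) ** 2
    freqs = np.array(
        [pseudo_frequency(a, sample_interval, spec.center_frequency) for a in scales]
    )
    return Scalogram(
        power=power,
        scales=scales,
        pseudo_frequencies=freqs,
        sample_interval=sample_interval,
        coi_halfwidth=_coi_halfwidths(scales, spec.bandwidth),
    )
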