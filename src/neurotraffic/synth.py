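"""Synthetic multichannel EEG with known ground truth.

Real resting-state recordings for this analysis are not publicly
deposited, so every pipeline stage is exercised on surrogates emulating
the study design: N subjects x 2 paired conditions (alternating epochs,
4 per condition), 30 s epochs at 500 Hz over up to 128 channels.

Each channel mixes 1/f Gaussian background with band-limited oscillatory
bursts.  Burst onsets form a renewal process with Gamma-distributed
inter-burst intervals, so the regularity of the burst envelope — and
hence the shape parameter recovered downstream from scalogram-trough
inter-departure times — is controlled by a single ground-truth knob.  A
condition effect perturbs that renewal shape (not overall power) on a
designated subset of channels, so condition differences cannot be
mimicked by a simple power-spectral-density change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .departures import IDTSample
from .preprocess import preprocess_recording
from .recording import EpochedRecording

__all__ = [
    "SynthSpec",
    "one_over_f_noise",
    "generate_subject",
    "generate_eeg",
    "generate_gamma_sample",
    "generate_preprocessed_epochs",
]


@dataclass(frozen=True)
class SynthSpec:
    """Design of a synthetic resting-state dataset.

    Defaults mirror the emulated study: 56 subjects, 128 channels,
    500 Hz, two alternating conditions with 4 epochs of 30 s each.

    Parameters
    ----------
    bands : tuple of (center_hz, amplitude)
        Oscillatory components, each gated by its own burst envelope.
    noise_exponent : float
        Spectral slope of the background: power ~ 1/f**noise_exponent.
    burst_shape : float
        Gamma shape of the inter-burst renewal intervals; higher = more
        regular bursting (lower envelope CV).
    mean_interval_cycles : float
        Mean inter-burst interval in cycles of the band's center
        frequency.
    effect_channels : tuple of int
        Channels on which condition 2 perturbs envelope regularity.
    effect_magnitude : float
        Fractional change of ``burst_shape`` in condition 2 on the
        effect channels; 0 builds a true null dataset.
    subject_sd : float
        SD of the per-subject log-normal multiplier on ``burst_shape``
        (individual differences).
    """

    n_subjects: int = 56
    n_channels: int = 128
    n_conditions: int = 2
    epochs_per_condition: int = 4
    epoch_duration: float = 30.0
    sampling_rate: float = 500.0
    bands: tuple = ((10.0, 1.0),)
    noise_exponent: float = 1.0
    noise_amplitude: float = 0.5
    burst_shape: float = 3.0
    mean_interval_cycles: float = 4.0
    effect_channels: tuple = ()
    effect_magnitude: float = 0.0
    subject_sd: float = 0.1
    condition_names: tuple = ("eyes_open", "eyes_closed")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_conditions != len(self.condition_names):
            raise ValueError("condition_names must match n_conditions")
        if any(c >= self.n_channels or c < 0 for c in self.effect_channels):
            raise ValueError("effect_channels must be a subset of channels")
        nyq = self.sampling_rate / 2.0
        if any(f >= nyq / 1.0 for f, _ in self.bands):
            raise ValueError("sampling_rate must exceed 2 x highest band center")
        if any(a < 0 for _, a in self.bands):
            raise ValueError("band amplitudes must be >= 0")

    @property
    def n_epochs(self) -> int:
        return self.n_conditions * self.epochs_per_condition

    @property
    def epoch_labels(self) -> tuple:
        # alternating conditions, as in the emulated protocol
        return tuple(
            self.condition_names[i % self.n_conditions] for i in range(self.n_epochs)
        )


def one_over_f_noise(
    n_samples: int, exponent: float, sfreq: float, rng: np.random.Generator
) -> np.ndarray:
    """Gaussian noise with power spectral density ~ 1/f**exponent, unit SD."""
    white = rng.standard_normal(n_samples)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sfreq)
    scale = np.zeros_like(freqs)
    scale[1:] = freqs[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * scale, n=n_samples)
    sd = x.std()
    return x / sd if sd > 0 else x


def _burst_envelope(
    duration: float,
    sfreq: float,
    center_hz: float,
    shape: float,
    mean_interval_cycles: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sum of Gaussian bumps at Gamma-renewal onset times."""
    mean_iv = mean_interval_cycles / center_hz
    theta = mean_iv / shape
    # draw enough intervals to cover the epoch with margin
    n_draw = int(duration / mean_iv * 2) + 10
    times = np.cumsum(rng.gamma(shape, theta, size=n_draw))
    times = times[times < duration]
    t = np.arange(int(round(duration * sfreq))) / sfreq
    env = np.zeros_like(t)
    width = 0.5 / center_hz  # bump SD: half a cycle
    for t0 in times:
        lo = max(0, int((t0 - 4 * width) * sfreq))
        hi = min(t.size, int((t0 + 4 * width) * sfreq) + 1)
        env[lo:hi] += np.exp(-0.5 * ((t[lo:hi] - t0) / width) ** 2)
    return env


def generate_subject(spec: SynthSpec, subject_index: int) -> EpochedRecording:
    """One subject's epoched recording, reproducible from the spec seed."""
    ss = np.random.SeedSequence(entropy=spec.seed, spawn_key=(subject_index,))
    rng = np.random.default_rng(ss)
    n_samp = int(round(spec.epoch_duration * spec.sampling_rate))
    subj_mult = float(np.exp(rng.normal(0.0, spec.subject_sd)))
    data = np.empty((spec.n_epochs, spec.n_channels, n_samp))
    labels = spec.epoch_labels
    for e, label in enumerate(labels):
        is_alt = label == spec.condition_names[-1]
        for c in range(spec.n_channels):
            x = spec.noise_amplitude * one_over_f_noise(
                n_samp, spec.noise_exponent, spec.sampling_rate, rng
            )
            shape = spec.burst_shape * subj_mult
            if is_alt and c in spec.effect_channels:
                shape = shape * (1.0 + spec.effect_magnitude)
            for center_hz, amp in spec.bands:
                if amp == 0:
                    continue
                env = _burst_envelope(
                    spec.epoch_duration, spec.sampling_rate, center_hz,
                    shape, spec.mean_interval_cycles, rng,
                )
                t = np.arange(n_samp) / spec.sampling_rate
                phase = rng.uniform(0, 2 * np.pi)
                x = x + amp * env * np.cos(2 * np.pi * center_hz * t + phase)
            data[e, c] = x
    return EpochedRecording(
        data=data,
        sfreq=spec.sampling_rate,
        condition_labels=labels,
        subject=f"s{subject_index:03d}",
    )


def generate_eeg(spec: SynthSpec) -> list[EpochedRecording]:
    """All subjects' recordings (use :func:`generate_subject` to stream)."""
    return [generate_subject(spec, i) for i in range(spec.n_subjects)]


def generate_gamma_sample(
    shape: float, scale: float, n: int, seed: int | np.random.Generator
) -> IDTSample:
    """n independent Gamma(shape, scale) draws as an interval sample."""
    if shape <= 0 or scale <= 0:
        raise ValueError("shape and scale must be > 0")
    rng = np.random.default_rng(seed)
    return IDTSample(rng.gamma(shape, scale, size=n))


def generate_preprocessed_epochs(
    spec: SynthSpec,
    recordings: list[EpochedRecording] | None = None,
    **preprocess_kwargs,
) -> list[EpochedRecording]:
    """Generate (or take) recordings and apply the standard preprocessing:
    0.5-55 Hz band-pass, 60 Hz notch, middle-20 s trim, per-epoch
    demeaning.  Epochs shorter than the trim window raise."""
    if recordings is None:
        recordings = generate_eeg(spec)
    return [preprocess_recording(rec, **preprocess_kwargs) for rec in recordings]
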