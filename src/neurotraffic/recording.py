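"""The in-memory container for multichannel epoched EEG."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["EpochedRecording"]


@dataclass(frozen=True)
class EpochedRecording:
    """Fixed-length condition-labelled epochs of a multichannel recording.

    Attributes
    ----------
    data : ndarray, shape (n_epochs, n_channels, n_samples)
        Signal in arbitrary voltage units.
    sfreq : float
        Sampling rate in Hz.
    condition_labels : tuple of str
        One label per epoch.
    subject : str or int
        Subject identifier.
    channel_names : tuple of str, optional
        Defaults to ch000, ch001, ...
    """

    data: np.ndarray
    sfreq: float
    condition_labels: tuple
    subject: str | int = "s0"
    channel_names: tuple = ()

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 3:
            raise ValueError("data must be (epochs, channels, samples)")
        if self.sfreq <= 0:
            raise ValueError("sfreq must be > 0")
        labels = tuple(self.condition_labels)
        if len(labels) != data.shape[0]:
            raise ValueError("one condition label per epoch required")
        names = tuple(self.channel_names) or tuple(
            f"ch{c:03d}" for c in range(data.shape[1])
        )
        if len(names) != data.shape[1]:
            raise ValueError("one channel name per channel required")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "condition_labels", labels)
        object.__setattr__(self, "channel_names", names)

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def sample_interval(self) -> float:
        return 1.0 / self.sfreq

    @property
    def conditions(self) -> tuple:
        seen: list = []
        for c in self.condition_labels:
            if c not in seen:
                seen.append(c)
        return tuple(seen)

    def epochs_of(self, condition) -> np.ndarray:
        """Indices of the epochs carrying one condition label."""
        return np.array(
            [i for i, c in enumerate(self.condition_labels) if c == condition]
        )
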