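"""Message-departure detection: thresholded scalogram troughs and
inter-departure times.

A "message departure" is a local minimum of the wavelet power time series
at one channel and one scale.  To suppress minute, insignificant troughs,
a candidate minimum must have topographic prominence of at least a fixed
ratio (default 5%) of the range (max - min) of the series it sits in: on
both sides, power must rise by at least that much before a deeper minimum
is reached (at a series end, the rise toward the end suffices).  The time
between successive departures, tau, is kept in digitization intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .timefreq import Scalogram

__all__ = [
    "DepartureTrain",
    "IDTSample",
    "detect_departures",
    "inter_departure_times",
    "extract_idt_table",
]


@dataclass(frozen=True)
class DepartureTrain:
    """Ordered departure events at one channel/scale series.

    ``event_indices`` are strictly increasing sample positions of the
    surviving troughs; a flat run of equal minima yields one event at the
    run's midpoint (rounded down).
    """

    event_indices: np.ndarray
    threshold_ratio: float
    channel_id: int | str | None = None
    scale_index: int | None = None

    def __post_init__(self) -> None:
        idx = np.asarray(self.event_indices, dtype=np.int64)
        if idx.size and np.any(np.diff(idx) <= 0):
            raise ValueError("event_indices must be strictly increasing")
        object.__setattr__(self, "event_indices", idx)

    def __len__(self) -> int:
        return int(self.event_indices.size)


@dataclass(frozen=True)
class IDTSample:
    """Positive inter-departure intervals tau, in digitization intervals.

    Intervals produced by trough detection are integer sample differences
    and therefore >= 1; the container itself only requires positivity so
    it can also hold continuous surrogate samples (e.g. Gamma draws).
    """

    intervals: np.ndarray
    sample_interval: float | None = None

    def __post_init__(self) -> None:
        iv = np.asarray(self.intervals, dtype=float)
        if iv.size and iv.min() <= 0:
            raise ValueError("intervals must be strictly positive durations")
        object.__setattr__(self, "intervals", iv)

    @property
    def n(self) -> int:
        return int(self.intervals.size)

    def to_ms(self) -> np.ndarray:
        """Intervals converted to milliseconds (requires sample_interval)."""
        if self.sample_interval is None:
            raise ValueError("sample_interval unknown; cannot convert to ms")
        return self.intervals * self.sample_interval * 1e3

    def pooled_with(self, other: "IDTSample") -> "IDTSample":
        return IDTSample(
            np.concatenate([self.intervals, other.intervals]),
            self.sample_interval or other.sample_interval,
        )


def detect_departures(
    power_series: np.ndarray,
    threshold_ratio: float = 0.05,
    channel_id: int | str | None = None,
    scale_index: int | None = None,
    coi_halfwidth: int = 0,
    drop_coi: bool = True,
) -> DepartureTrain:
    """Find every interior trough whose prominence clears the threshold.

    Parameters
    ----------
    power_series : 1-D array
        Nonnegative wavelet power at one channel and scale.
    threshold_ratio : float in [0, 1)
        Prominence floor as a fraction of the series range (max - min).
        The published analysis used 0.05 and found 0.02-0.10 equivalent.
    coi_halfwidth : int
        Cone-of-influence half-width in samples; with ``drop_coi`` (the
        default) events within that many samples of either edge are
        discarded as padding artifacts.

    Returns
    -------
    DepartureTrain
        Events sorted ascending.  A constant series yields an empty train.
    """
    x = np.asarray(power_series, dtype=float)
    if x.ndim != 1:
        raise ValueError("power_series must be 1-D")
    if x.size < 3:
        raise ValueError("power_series must have length >= 3")
    if not np.all(np.isfinite(x)):
        raise ValueError("power_series contains NaN or infinite values")
    if not 0 <= threshold_ratio < 1:
        raise ValueError("threshold_ratio must lie in [0, 1)")

    rng = float(x.max() - x.min())
    if rng == 0.0:
        return DepartureTrain(np.empty(0, dtype=np.int64), threshold_ratio,
                              channel_id, scale_index)

    events, _ = find_peaks(-x, prominence=threshold_ratio * rng)
    if drop_coi and coi_halfwidth > 0:
        events = events[(events >= coi_halfwidth) & (events < x.size - coi_halfwidth)]
    return DepartureTrain(events, threshold_ratio, channel_id, scale_index)


def inter_departure_times(
    train: DepartureTrain, sample_interval: float | None = None
) -> IDTSample:
    """Differences between successive departures of one train.

    Raises
    ------
    ValueError
        If the train has fewer than two events (no interval can be formed).
    """
    if len(train) < 2:
        raise ValueError(
            f"need >= 2 departure events to form intervals, got {len(train)}"
        )
    return IDTSample(np.diff(train.event_indices).astype(float), sample_interval)


def extract_idt_table(
    scalograms: Mapping[tuple, Scalogram] | Iterable[tuple[tuple, Scalogram]],
    threshold_ratio: float = 0.05,
    drop_coi: bool = True,
) -> dict[tuple, IDTSample]:
    """Pool inter-departure times per (subject, condition, channel, frequency).

    Parameters
    ----------
    scalograms : mapping
        ``(subject, condition, epoch) -> Scalogram``.  Each epoch is
        searched independently; intervals never span an epoch boundary.
        Epochs of the same (subject, condition) cell are pooled.

    Returns
    -------
    dict
        ``(subject, condition, channel, frequency_hz) -> IDTSample``.
        Cells in which no epoch produced >= 2 events are flagged by an
        empty sample (n == 0), never fabricated.
    """
    items = scalograms.items() if hasattr(scalograms, "items") else scalograms
    pooled: dict[tuple, list[np.ndarray]] = {}
    dt_by_cell: dict[tuple, float] = {}
    for (subject, condition, _epoch), scg in items:
        for ch in range(scg.n_channels):
            for si, freq in enumerate(scg.pseudo_frequencies):
                train = detect_departures(
                    scg.power[ch, si],
                    threshold_ratio,
                    channel_id=ch,
                    scale_index=si,
                    coi_halfwidth=int(scg.coi_halfwidth[si]),
                    drop_coi=drop_coi,
                )
                key = (subject, condition, ch, round(float(freq), 6))
                pooled.setdefault(key, [])
                dt_by_cell[key] = scg.sample_interval
                if len(train) >= 2:
                    pooled[key].append(np.diff(train.event_indices).astype(float))
    return {
        key: IDTSample(
            np.concatenate(chunks) if chunks else np.empty(0), dt_by_cell[key]
        )
        for key, chunks in pooled.items()
    }


def idt_table_to_frame(table: Mapping[tuple, IDTSample]) -> pd.DataFrame:
    """Long-format view: one row per interval, for delimited-text export."""
    rows = []
    for (subject, condition, channel, freq), sample in table.items():
        for tau in sample.intervals:
            rows.append((subject, condition, channel, freq, tau))
    return pd.DataFrame(
        rows, columns=["subject", "condition", "channel", "frequency_hz", "tau_samples"]
    )
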