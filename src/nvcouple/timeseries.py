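"""Uniformly sampled time series container used throughout the package."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class TimeSeries:
    """A uniformly sampled real-valued signal.

    Parameters
    ----------
    values : array-like
        Sample values.
    fs : float
        Sampling rate in Hz. Must be positive.
    t0 : float, optional
        Time of the first sample in seconds (default 0).
    """

    values: np.ndarray
    fs: float
    t0: float = 0.0
    _times: np.ndarray = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("TimeSeries values must be one-dimensional")
        if not np.isfinite(self.values).all():
            raise ValueError("TimeSeries values must be finite")
        if not (self.fs > 0):
            raise ValueError(f"sampling rate must be positive, got {self.fs}")

    def __len__(self) -> int:
        return self.values.size

    @property
    def dt(self) -> float:
        return 1.0 / self.fs

    @property
    def duration(self) -> float:
        """Duration in seconds (n samples / fs)."""
        return len(self) / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self)) / self.fs

    def index_of(self, t: float) -> int:
        """Index of the sample nearest to time ``t`` (seconds)."""
        return int(round((t - self.t0) * self.fs))

    def slice_time(self, start: float, stop: float) -> "TimeSeries":
        """Samples in the half-open time interval [start, stop)."""
        i0 = self.index_of(start)
        i1 = self.index_of(stop)
        if i0 < 0 or i1 > len(self):
            raise ValueError(
                f"slice [{start}, {stop}) s is outside the recording "
                f"[{self.t0}, {self.t0 + self.duration}) s"
            )
        return TimeSeries(self.values[i0:i1], self.fs, t0=self.t0 + i0 / self.fs)

    def copy_with(self, values: np.ndarray) -> "TimeSeries":
        """A new series with the same time base but different values."""
        return TimeSeries(np.asarray(values, dtype=float), self.fs, self.t0)
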