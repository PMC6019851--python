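"""Shared containers for uniformly sampled fNIRS signals.

Every signal in this package — simulated HbO concentration change,
optical density at one wavelength, a hemodynamic kernel — is a scalar
series on a uniform time grid.  :class:`TimeSeries` carries the sample
values together with the sampling rate and time origin so that
operations can check grid compatibility instead of silently assuming
it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["TimeSeries"]

#: Relative tolerance when deciding two sampling rates are "the same grid".
FS_RTOL = 1e-9


@dataclass
class TimeSeries:
    """A uniformly sampled scalar signal.

    Parameters
    ----------
    values : array-like of float
        Sample values, one per time step.
    fs : float
        Sampling rate in Hz; must be positive.
    t0 : float, optional
        Time of the first sample in seconds (default 0).
    """

    values: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("TimeSeries values must be one-dimensional")
        if not np.isfinite(self.fs) or self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")

    def __len__(self) -> int:
        return self.values.size

    @property
    def dt(self) -> float:
        """Sample spacing in seconds."""
        return 1.0 / self.fs

    @property
    def times(self) -> np.ndarray:
        """Time stamps in seconds, ``t0 + k / fs``."""
        return self.t0 + np.arange(self.values.size) / self.fs

    @property
    def duration(self) -> float:
        """Span from the first to the last sample, in seconds."""
        return 0.0 if len(self) == 0 else (len(self) - 1) / self.fs

    def same_grid(self, other: "TimeSeries") -> bool:
        return (
            len(self) == len(other)
            and np.isclose(self.fs, other.fs, rtol=FS_RTOL)
            and np.isclose(self.t0, other.t0, atol=1e-9)
        )

    def copy_with(self, values: np.ndarray) -> "TimeSeries":
        """A new series on the same grid with different values."""
        return TimeSeries(np.asarray(values, dtype=float), self.fs, self.t0)

    # -- CSV interchange (columns: time_s, value) ----------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.times, "value": self.values})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, value_column: str = "value") -> "TimeSeries":
        frame = pd.read_csv(path)
        return cls.from_frame(frame, value_column=value_column)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, value_column: str = "value") -> "TimeSeries":
        t = np.asarray(frame["time_s"], dtype=float)
        if t.size < 2:
            raise ValueError("need at least two samples to infer a sampling rate")
        steps = np.diff(t)
        dt = float(np.median(steps))
        if dt <= 0 or not np.allclose(steps, dt, rtol=1e-6, atol=1e-9):
            raise ValueError("time_s column is not a uniform grid")
        return cls(np.asarray(frame[value_column], dtype=float), fs=1.0 / dt, t0=float(t[0]))


def require_same_grid(a: TimeSeries, b: TimeSeries, what: str = "series") -> None:
    if not a.same_grid(b):
        raise ValueError(
            f"{what} are not on the same time grid "
            f"(n={len(a)}/{len(b)}, fs={a.fs}/{b.fs}, t0={a.t0}/{b.t0})"
        )
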