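"""Canonical hemodynamic response model and HRF attribute extraction.

The hemodynamic impulse response is the standard double-gamma kernel

    h(t) = g(t; α1, β1) - g(t; α2, β2) / 6,

where ``g`` is the gamma probability density with shape ``α`` and rate
``β``.  The first term is the main response (peaking near
``(α1 - 1)/β1`` seconds), the second a delayed undershoot attenuated by
the fixed divisor 6, which is part of the canonical form and not a free
parameter.  The predicted activity signal is the convolution of this
kernel with the boxcar encoding of the experimental stimulus train.

Attribute extraction reduces a response curve to the scalar features
the sensitivity analysis tracks: peak value, time to peak, full width
at half maximum, post-stimulus undershoot depth and baseline offset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import gammaln

from .core import TimeSeries, require_same_grid

__all__ = [
    "HRFParams",
    "StimulusTrain",
    "HRFAttributes",
    "canonical_kernel",
    "encode_stimulus",
    "convolve_hrf",
    "extract_attributes",
    "KERNEL_SUPPORT_S",
]

#: Kernel support in seconds.  The canonical response has settled well
#: before 32 s (baseline return at 25-30 s), so the kernel is truncated
#: there.
KERNEL_SUPPORT_S = 32.0


@dataclass(frozen=True)
class HRFParams:
    """Shape parameters of the double-gamma kernel.

    ``alpha1``/``beta1`` are shape and rate (1/s) of the main response,
    ``alpha2``/``beta2`` of the undershoot.  Both shapes must exceed 1
    so the kernel vanishes at t = 0 and has an interior peak.
    """

    alpha1: float = 6.0
    alpha2: float = 16.0
    beta1: float = 1.0
    beta2: float = 1.0

    def validate(self) -> None:
        if not (self.alpha1 > 1 and self.alpha2 > 1):
            raise ValueError("gamma shapes alpha1, alpha2 must exceed 1")
        if not (self.beta1 > 0 and self.beta2 >= 0):
            raise ValueError("beta1 must be positive and beta2 non-negative")


@dataclass(frozen=True)
class StimulusTrain:
    """Task blocks of an experimental paradigm.

    ``onsets`` and ``durations`` (seconds) describe non-overlapping
    activation blocks inside ``[0, total_length]``.
    """

    onsets: tuple[float, ...]
    durations: tuple[float, ...]
    total_length: float
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "onsets", tuple(float(t) for t in self.onsets))
        object.__setattr__(self, "durations", tuple(float(d) for d in self.durations))
        if len(self.onsets) != len(self.durations):
            raise ValueError("onsets and durations must have equal length")
        if any(d <= 0 for d in self.durations):
            raise ValueError("durations must be positive")
        prev_end = 0.0
        for onset, dur in zip(self.onsets, self.durations):
            if onset < prev_end:
                raise ValueError("task blocks must be ordered and non-overlapping")
            prev_end = onset + dur
        if prev_end > self.total_length + 1e-9:
            raise ValueError("task blocks extend past total_length")

    @property
    def offsets(self) -> tuple[float, ...]:
        return tuple(o + d for o, d in zip(self.onsets, self.durations))

    @property
    def task_window(self) -> tuple[float, float]:
        """(first onset, last offset) in seconds."""
        return self.onsets[0], self.offsets[-1]


@dataclass(frozen=True)
class HRFAttributes:
    """Scalar features of one response curve.

    ``undershoot_depth`` is the magnitude of the post-stimulus dip below
    baseline (clipped at 0); ``fwhm_s`` is NaN when the curve has no
    positive main response above baseline.
    """

    peak_value: float
    time_to_peak_s: float
    fwhm_s: float
    undershoot_depth: float
    baseline_offset: float

    FIELDS = ("peak_value", "time_to_peak_s", "fwhm_s", "undershoot_depth", "baseline_offset")

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in self.FIELDS}


def canonical_kernel(params: HRFParams, dt: float, length: float = KERNEL_SUPPORT_S) -> TimeSeries:
    """Sample the double-gamma kernel on ``t = 0, dt, ..., length``.

    The two terms are gamma densities in shape/rate form; the second is
    divided by the fixed attenuation constant 6.
    """
    if dt <= 0 or length <= 0:
        raise ValueError("dt and length must be positive")
    params.validate()
    t = np.arange(0.0, length + dt / 2, dt)
    values = _gamma_pdf(t, params.alpha1, params.beta1) - _gamma_pdf(t, params.alpha2, params.beta2) / 6.0
    return TimeSeries(values, fs=1.0 / dt)


def _gamma_pdf(t: np.ndarray, shape: float, rate: float) -> np.ndarray:
    """Gamma density t^(a-1) b^a e^(-bt) / Γ(a), zero for t <= 0 and for b = 0."""
    if rate == 0.0:
        return np.zeros_like(t)
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]
    out[pos] = np.exp(
        (shape - 1.0) * np.log(tp) - rate * tp + shape * math.log(rate) - gammaln(shape)
    )
    return out


def encode_stimulus(train: StimulusTrain, fs: float) -> TimeSeries:
    """Unit boxcar encoding of a stimulus train: 1 during task, 0 at rest."""
    if fs <= 0:
        raise ValueError("fs must be positive")
    n = int(round(train.total_length * fs)) + 1
    u = np.zeros(n)
    t = np.arange(n) / fs
    for onset, offset in zip(train.onsets, train.offsets):
        u[(t >= onset - 1e-9) & (t < offset - 1e-9)] = 1.0
    return TimeSeries(u, fs=fs)


def convolve_hrf(u: TimeSeries, h: TimeSeries, dt: float | None = None) -> TimeSeries:
    """Discrete convolution ``(u * h) dt`` truncated to ``u``'s length.

    ``u`` and ``h`` must share the sampling step; a single-sample unit
    impulse of mass ``1/dt`` reproduces ``h``.
    """
    if dt is None:
        dt = u.dt
    if not (np.isclose(u.dt, dt, rtol=1e-9) and np.isclose(h.dt, dt, rtol=1e-9)):
        raise ValueError(
            f"stimulus and kernel sample steps differ: {u.dt} vs {h.dt} (expected {dt})"
        )
    from scipy.signal import fftconvolve

    full = fftconvolve(u.values, h.values)[: len(u)] * dt
    return TimeSeries(full, fs=u.fs, t0=u.t0)


def extract_attributes(
    series: TimeSeries,
    task_window: tuple[float, float],
    peak_search_pad_s: float = 10.0,
) -> HRFAttributes:
    """Reduce a response curve to its scalar HRF features.

    * ``baseline_offset``: mean over the pre-onset rest.
    * ``peak_value`` / ``time_to_peak_s``: global maximum inside
      ``[onset, offset + peak_search_pad_s]``; time is measured from the
      task onset.
    * ``fwhm_s``: width between the half-maximum crossings bracketing
      the peak, measured above baseline, with crossings located by
      linear interpolation; NaN if the curve never rises above baseline
      or a crossing is missing.
    * ``undershoot_depth``: ``max(0, baseline - min)`` over the window
      from task offset to the end of the series.

    The series must cover the task window; ties at the maximum are
    broken by the earliest time.
    """
    onset, offset = task_window
    if offset <= onset:
        raise ValueError("task window must have positive length")
    t = series.times
    if onset < t[0] - 1e-9 or offset > t[-1] + 1e-9:
        raise ValueError("task window lies outside the series span")
    y = series.values

    pre = y[t < onset - 1e-9]
    baseline = float(pre.mean()) if pre.size else float(y[0])

    search = (t >= onset - 1e-9) & (t <= offset + peak_search_pad_s + 1e-9)
    idx_search = np.flatnonzero(search)
    seg = y[idx_search]
    peak_local = int(np.argmax(seg))  # argmax returns the first maximum
    peak_idx = int(idx_search[peak_local])
    peak_value = float(y[peak_idx])
    time_to_peak = float(t[peak_idx] - onset)

    fwhm = _fwhm(t, y, peak_idx, baseline)

    post = y[t > offset + 1e-9]
    undershoot = float(max(0.0, baseline - post.min())) if post.size else 0.0

    return HRFAttributes(
        peak_value=peak_value,
        time_to_peak_s=time_to_peak,
        fwhm_s=fwhm,
        undershoot_depth=undershoot,
        baseline_offset=baseline,
    )


def _fwhm(t: np.ndarray, y: np.ndarray, peak_idx: int, baseline: float) -> float:
    amplitude = y[peak_idx] - baseline
    if amplitude <= 0:
        return float("nan")
    half = baseline + amplitude / 2.0

    left = _cross_time(t, y, peak_idx, half, step=-1)
    right = _cross_time(t, y, peak_idx, half, step=+1)
    if left is None or right is None:
        return float("nan")
    return right - left


def _cross_time(t: np.ndarray, y: np.ndarray, start: int, level: float, step: int) -> float | None:
    """Time where y crosses `level` walking from `start`, linearly interpolated."""
    i = start
    while 0 <= i + step < len(y):
        j = i + step
        if y[j] < level:
            # crossing between samples i and j
            frac = (y[i] - level) / (y[i] - y[j])
            return float(t[i] + frac * (t[j] - t[i]))
        i = j
    return None
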