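"""Synthetic fNIRS signal generation.

No subject data accompany the analysis, so the study conditions are
reproduced by simulation.  The observed HbO series at one channel is
modelled as

    y(k) = a0 + a1·HRF(k) + ac·sin(2π fc k) + ar·sin(2π fr k)
                         + am·sin(2π fm k) + ε(k),

a baseline plus the stimulus-convolved hemodynamic response scaled by
an activity strength, three physiological nuisance sinusoids (cardiac,
respiratory and Mayer waves) and zero-mean Gaussian noise.  Time ``k``
is in seconds and the sinusoids have zero phase.

Two paradigms are provided: the real-protocol block design (15 s rest,
then four 15 s task / 15 s rest trials) and the simulation paradigms
(10 s rest, a stimulus train St1-St5 of 10/20/30 s blocks, 30 s final
rest).  Signals are generated at the acquisition rate and resampled to
the analysis grid by linear interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core import TimeSeries
from .hemodynamics import HRFParams, StimulusTrain, canonical_kernel, convolve_hrf, encode_stimulus

__all__ = [
    "NuisanceParams",
    "generate_signal",
    "paper_paradigm",
    "simulated_paradigm",
    "resample_to",
    "STIMULUS_PATTERNS",
    "ACQUISITION_FS_HZ",
    "ANALYSIS_FS_HZ",
]

#: Acquisition and analysis sampling rates (Hz).
ACQUISITION_FS_HZ = 1.81
ANALYSIS_FS_HZ = 100.0

#: Default task durations (s) of the simulation paradigms.
SIMULATED_TASK_DURATIONS_S = (10.0, 20.0, 30.0)


@dataclass(frozen=True)
class NuisanceParams:
    """Baseline, activity strength and physiological nuisance terms.

    Amplitudes are in signal units, frequencies in Hz.  Defaults put
    the cardiac, respiratory and Mayer components at typical resting
    frequencies; ``noise_sd`` defaults to 0.1 signal units (use 0 for
    recovery experiments).
    """

    a0: float = 0.0
    a1: float = 1.0
    ac: float = 0.0
    ar: float = 0.0
    am: float = 0.0
    fc: float = 1.1
    fr: float = 0.25
    fm: float = 0.095
    noise_sd: float = 0.1
    seed: int | None = None

    def __post_init__(self) -> None:
        if min(self.ac, self.ar, self.am) < 0:
            raise ValueError("sinusoid amplitudes must be non-negative")
        if min(self.fc, self.fr, self.fm) <= 0:
            raise ValueError("sinusoid frequencies must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def generate_signal(
    hrf_params: HRFParams,
    nuisance: NuisanceParams,
    paradigm: StimulusTrain,
    fs: float,
    seed: int | None = None,
) -> TimeSeries:
    """Simulate one channel of the optical signal model.

    The HRF term is the double-gamma kernel convolved with the
    paradigm's unit boxcar.  Every sinusoid with nonzero amplitude must
    be representable at ``fs`` (``fs > 2 f``); the acquisition rate of
    1.81 Hz therefore only admits sub-0.9 Hz nuisance terms.  The seed
    (argument, falling back to ``nuisance.seed``) makes the Gaussian
    noise reproducible.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    for name, amp, freq in (
        ("cardiac", nuisance.ac, nuisance.fc),
        ("respiratory", nuisance.ar, nuisance.fr),
        ("Mayer", nuisance.am, nuisance.fm),
    ):
        if amp > 0 and fs <= 2.0 * freq:
            raise ValueError(
                f"fs={fs} Hz aliases the {name} sinusoid at {freq} Hz; "
                f"need fs > {2.0 * freq} Hz"
            )

    u = encode_stimulus(paradigm, fs)
    h = canonical_kernel(hrf_params, dt=1.0 / fs)
    hrf = convolve_hrf(u, h)
    t = u.times

    y = nuisance.a0 + nuisance.a1 * hrf.values
    for amp, freq in ((nuisance.ac, nuisance.fc), (nuisance.ar, nuisance.fr), (nuisance.am, nuisance.fm)):
        if amp != 0.0:
            y = y + amp * np.sin(2.0 * np.pi * freq * t)
    if nuisance.noise_sd > 0:
        rng = np.random.default_rng(seed if seed is not None else nuisance.seed)
        y = y + rng.normal(0.0, nuisance.noise_sd, size=t.size)
    return TimeSeries(y, fs=fs)


def paper_paradigm() -> StimulusTrain:
    """The real-protocol block design.

    15 s initial rest, then four trials of 15 s task + 15 s rest:
    onsets at 15, 45, 75 and 105 s, 135 s total.
    """
    return StimulusTrain(
        onsets=(15.0, 45.0, 75.0, 105.0),
        durations=(15.0,) * 4,
        total_length=135.0,
        label="paper",
    )


# Block layout of the simulation stimulus trains St1-St5, as
# (gap_before_block_s, duration_scale) pairs; the first gap is measured
# from the end of the initial rest.  The trains are not fixed by the
# source protocol beyond their count, so these defaults are explicit
# configuration: St1 a single block, St2/St4 double blocks with long and
# short gaps, St3 a triple train, St5 a full block followed by a
# half-duration block.
STIMULUS_PATTERNS: dict[str, tuple[tuple[float, float], ...]] = {
    "St1": ((0.0, 1.0),),
    "St2": ((0.0, 1.0), (20.0, 1.0)),
    "St3": ((0.0, 1.0), (15.0, 1.0), (15.0, 1.0)),
    "St4": ((0.0, 1.0), (10.0, 1.0)),
    "St5": ((0.0, 1.0), (15.0, 0.5)),
}

INITIAL_REST_S = 10.0
TERMINAL_REST_S = 30.0


def simulated_paradigm(
    task_s: float,
    pattern: str,
    patterns: dict[str, tuple[tuple[float, float], ...]] | None = None,
) -> StimulusTrain:
    """Simulation paradigm: 10 s rest, a stimulus train, 30 s rest.

    ``task_s`` is the nominal block duration (10, 20 or 30 s in the
    study conditions; other positive values are accepted with a
    warning).  ``pattern`` selects one of the trains in
    ``STIMULUS_PATTERNS`` (or a user-supplied ``patterns`` dict).
    """
    if task_s <= 0:
        raise ValueError("task duration must be positive")
    if task_s not in SIMULATED_TASK_DURATIONS_S:
        import warnings

        warnings.warn(
            f"task duration {task_s} s is outside the study set {SIMULATED_TASK_DURATIONS_S}",
            stacklevel=2,
        )
    table = STIMULUS_PATTERNS if patterns is None else patterns
    if pattern not in table:
        raise ValueError(f"unknown stimulus pattern {pattern!r}; known: {sorted(table)}")

    onsets, durations = [], []
    cursor = INITIAL_REST_S
    for gap, scale in table[pattern]:
        cursor += gap
        onsets.append(cursor)
        durations.append(task_s * scale)
        cursor += task_s * scale
    return StimulusTrain(
        onsets=tuple(onsets),
        durations=tuple(durations),
        total_length=cursor + TERMINAL_REST_S,
        label=pattern,
    )


def resample_to(series: TimeSeries, target_fs: float) -> TimeSeries:
    """Linear interpolation onto a uniform grid at ``target_fs``.

    The new grid starts at the series origin and covers the same
    interval (last grid point <= old last sample).  Linear
    interpolation is exact on piecewise-linear signals and keeps the
    operation deterministic.
    """
    if target_fs <= 0:
        raise ValueError("target_fs must be positive")
    if len(series) < 2:
        raise ValueError("need at least two samples to resample")
    t_old = series.times
    n_new = int(np.floor(series.duration * target_fs)) + 1
    t_new = series.t0 + np.arange(n_new) / target_fs
    return TimeSeries(np.interp(t_new, t_old, series.values), fs=target_fs, t0=series.t0)
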