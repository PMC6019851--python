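"""Box-constrained Nelder-Mead estimation of the HRF + nuisance model.

Given a measured two-wavelength optical-density pair and a DPF pair,
the HbO series is reconstructed with the fixed-coefficient relation and
fitted by the twelve-parameter signal model

    model(k) = a0 + a1·HRF(k; α1, α2, β1, β2)
             + ac·sin(2π fc k) + ar·sin(2π fr k) + am·sin(2π fm k),

minimising the squared-error cost J2 subject to the physiological box
constraints C1-C12:

    α1∈[2,10]  α2∈[6,20]  β1∈[0.5,2]  β2∈[0,1.5]
    a0∈[0,20]  a1∈[0,15]  ac,ar,am∈[0,2]
    fc∈[0.5,1.5]  fr∈[0.2,0.3]  fm∈[0.09,0.1]

The Nelder-Mead simplex (standard reflection/expansion/contraction/
shrink coefficients 1, 2, 0.5, 0.5) is run in an unconstrained space
obtained by a per-coordinate logistic bijection of the box, so every
trial point is interior by construction.  The cost is multimodal in
the sinusoid frequencies (local minima spaced roughly 1/T apart, with
T the record length), which a single simplex cannot escape.  The
search therefore proceeds in two phases: short simplex runs from
seeded uniform in-box starting points, then, for the best candidates,
alternating rounds of frequency reseeding (a one-dimensional scan of
each frequency over its box, all other parameters held fixed, jumping
to the best grid point) and full-length simplex runs.  Everything is
driven by one seeded generator, so identical inputs and seed give an
identical result.  Repeating the fit over a DPF grid (the 3-8 sweep)
and extracting HRF attributes from each fitted activity curve yields
the sensitivity table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit

from .core import TimeSeries
from .hemodynamics import (
    HRFAttributes,
    HRFParams,
    StimulusTrain,
    canonical_kernel,
    convolve_hrf,
    encode_stimulus,
    extract_attributes,
)
from .mbll import ODPair, reconstruct_hbo_paper

__all__ = [
    "PARAM_NAMES",
    "ParamVector",
    "ConstraintBox",
    "DEFAULT_BOX",
    "FitResult",
    "j2_cost",
    "fit",
    "sweep_fit",
    "SWEEP_COLUMNS",
]

PARAM_NAMES = (
    "alpha1", "alpha2", "beta1", "beta2",
    "a0", "a1", "ac", "ar", "am",
    "fc", "fr", "fm",
)


@dataclass(frozen=True)
class ParamVector:
    """The twelve free parameters of the signal model."""

    alpha1: float
    alpha2: float
    beta1: float
    beta2: float
    a0: float
    a1: float
    ac: float
    ar: float
    am: float
    fc: float
    fr: float
    fm: float

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, x: np.ndarray) -> "ParamVector":
        return cls(**dict(zip(PARAM_NAMES, map(float, x))))

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in PARAM_NAMES}

    @property
    def hrf_params(self) -> HRFParams:
        return HRFParams(self.alpha1, self.alpha2, self.beta1, self.beta2)


@dataclass(frozen=True)
class ConstraintBox:
    """Per-parameter lower/upper bounds (defaults: C1-C12)."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        lo = np.asarray(self.lower, dtype=float)
        hi = np.asarray(self.upper, dtype=float)
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", hi)
        if lo.shape != (len(PARAM_NAMES),) or hi.shape != (len(PARAM_NAMES),):
            raise ValueError("box must bound exactly the twelve parameters")
        if not np.all(hi > lo):
            raise ValueError("every upper bound must exceed its lower bound")

    def contains(self, params: ParamVector, atol: float = 1e-9) -> bool:
        x = params.to_array()
        return bool(np.all(x >= self.lower - atol) & np.all(x <= self.upper + atol))

    # -- logistic bijection box <-> R^12 -------------------------------

    def to_unconstrained(self, x: np.ndarray) -> np.ndarray:
        frac = (np.asarray(x, dtype=float) - self.lower) / (self.upper - self.lower)
        return logit(np.clip(frac, 1e-12, 1 - 1e-12))

    def from_unconstrained(self, z: np.ndarray) -> np.ndarray:
        return self.lower + (self.upper - self.lower) * expit(np.asarray(z, dtype=float))


DEFAULT_BOX = ConstraintBox(
    lower=np.array([2.0, 6.0, 0.5, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.5, 0.2, 0.09]),
    upper=np.array([10.0, 20.0, 2.0, 1.5, 20.0, 15.0, 2.0, 2.0, 2.0, 1.5, 0.3, 0.1]),
)


@dataclass
class FitResult:
    """Best model found by the multi-start simplex search."""

    best: ParamVector
    j2: float
    n_restarts_used: int
    n_iterations: int
    converged: bool
    seed: int | None
    dpf_l1: float
    dpf_l2: float

    def as_dict(self) -> dict:
        return {
            "params": self.best.as_dict(),
            "j2": self.j2,
            "n_restarts_used": self.n_restarts_used,
            "n_iterations": self.n_iterations,
            "converged": self.converged,
            "seed": self.seed,
            "dpf_l1": self.dpf_l1,
            "dpf_l2": self.dpf_l2,
        }


def _model_prediction(x: np.ndarray, u: TimeSeries, t: np.ndarray, fs: float) -> np.ndarray:
    alpha1, alpha2, beta1, beta2, a0, a1, ac, ar, am, fc, fr, fm = x
    h = canonical_kernel(HRFParams(alpha1, alpha2, beta1, beta2), dt=1.0 / fs)
    hrf = convolve_hrf(u, h).values
    return (
        a0
        + a1 * hrf
        + ac * np.sin(2.0 * np.pi * fc * t)
        + ar * np.sin(2.0 * np.pi * fr * t)
        + am * np.sin(2.0 * np.pi * fm * t)
    )


def j2_cost(
    params: ParamVector,
    pair: ODPair,
    paradigm: StimulusTrain,
    dpf_l1: float,
    dpf_l2: float,
    fs: float,
) -> float:
    """Squared-error cost of one parameter vector.

    The target is the HbO series reconstructed from the OD pair at the
    given DPFs; the cost is defined for out-of-box parameters too (the
    optimiser's trial points stay interior via the bijection, but the
    cost itself does not enforce the box).
    """
    target = reconstruct_hbo_paper(pair.od_l1, pair.od_l2, dpf_l1, dpf_l2)
    u = encode_stimulus(paradigm, fs)
    if len(u) != len(target):
        raise ValueError(
            f"paradigm grid ({len(u)} samples at {fs} Hz) does not match the "
            f"OD series ({len(target)} samples)"
        )
    r = _model_prediction(params.to_array(), u, u.times, fs) - target.values
    return float(r @ r)


#: Indices of the sinusoid frequencies in PARAM_NAMES order.
_FREQ_INDICES = (9, 10, 11)

#: Initial-simplex edge length in the unconstrained (logit) space.
_SIMPLEX_STEP = 0.5


def fit(
    pair: ODPair,
    paradigm: StimulusTrain,
    dpf_l1: float,
    dpf_l2: float,
    fs: float,
    n_restarts: int = 5,
    seed: int | None = 0,
    max_iter: int = 1500,
    ftol: float = 1e-10,
    box: ConstraintBox = DEFAULT_BOX,
    n_deep: int = 2,
    reseed_rounds: int = 2,
    freq_grid: int = 161,
) -> FitResult:
    """Multi-start box-constrained Nelder-Mead fit of the signal model.

    ``n_restarts`` short simplex probes (``max_iter // 3`` iterations
    each) start from seeded uniform in-box points; the ``n_deep`` best
    probes are refined by ``reseed_rounds`` rounds of frequency
    reseeding (a ``freq_grid``-point scan of each sinusoid frequency)
    followed by a full ``max_iter`` simplex run.  Identical seed and
    inputs give an identical result.  Exhausting the iteration budget
    without meeting ``ftol`` is reported via ``converged=False``,
    never raised.
    """
    target = reconstruct_hbo_paper(pair.od_l1, pair.od_l2, dpf_l1, dpf_l2)
    u = encode_stimulus(paradigm, fs)
    if len(u) != len(target):
        raise ValueError(
            f"paradigm grid ({len(u)} samples at {fs} Hz) does not match the "
            f"OD series ({len(target)} samples)"
        )
    if n_restarts < 1:
        raise ValueError("n_restarts must be at least 1")
    t = u.times
    tv = target.values

    def cost_x(x: np.ndarray) -> float:
        r = _model_prediction(x, u, t, fs) - tv
        return float(r @ r)

    def cost_z(z: np.ndarray) -> float:
        return cost_x(box.from_unconstrained(z))

    total_iter = 0
    converged = False

    def simplex(z0: np.ndarray, maxiter: int):
        nonlocal total_iter, converged
        n = z0.size
        init = np.tile(z0, (n + 1, 1))
        for i in range(n):
            init[i + 1, i] += _SIMPLEX_STEP
        res = minimize(
            cost_z,
            z0,
            method="Nelder-Mead",
            options={
                "maxiter": maxiter,
                "maxfev": 2 * maxiter,
                "fatol": ftol,
                "xatol": 1e-10,
                "initial_simplex": init,
            },
        )
        total_iter += int(res.nit)
        converged = converged or bool(res.success)
        return float(res.fun), res.x

    def freq_reseed(z: np.ndarray) -> np.ndarray:
        x = box.from_unconstrained(z)
        for i in _FREQ_INDICES:
            grid = np.linspace(box.lower[i] + 1e-9, box.upper[i] - 1e-9, freq_grid)
            trial = x.copy()
            costs = []
            for g in grid:
                trial[i] = g
                costs.append(cost_x(trial))
            x[i] = grid[int(np.argmin(costs))]
        return box.to_unconstrained(x)

    rng = np.random.default_rng(seed)
    probes = []
    for _ in range(n_restarts):
        z0 = box.to_unconstrained(rng.uniform(box.lower, box.upper))
        probes.append(simplex(z0, max(50, max_iter // 3)))
    probes.sort(key=lambda p: p[0])

    best_cost, best_z = probes[0]
    for cost, z in probes[: max(1, n_deep)]:
        for _ in range(max(1, reseed_rounds)):
            z_new = freq_reseed(z)
            new_cost, z_cand = simplex(z_new, max_iter)
            if new_cost < cost:
                cost, z = new_cost, z_cand
        if cost < best_cost:
            best_cost, best_z = cost, z

    return FitResult(
        best=ParamVector.from_array(box.from_unconstrained(best_z)),
        j2=best_cost,
        n_restarts_used=n_restarts,
        n_iterations=total_iter,
        converged=converged,
        seed=seed,
        dpf_l1=dpf_l1,
        dpf_l2=dpf_l2,
    )


SWEEP_COLUMNS = (
    "label", "case", "dpf_l1", "dpf_l2",
    "peak_value", "time_to_peak_s", "fwhm_s", "undershoot_depth", "baseline_offset",
    "j2", "converged", "error",
)


def fitted_activity_curve(result: FitResult, paradigm: StimulusTrain, fs: float) -> TimeSeries:
    """The fitted ``a0 + a1·HRF`` curve (nuisance sinusoids removed)."""
    u = encode_stimulus(paradigm, fs)
    h = canonical_kernel(result.best.hrf_params, dt=1.0 / fs)
    hrf = convolve_hrf(u, h)
    return hrf.copy_with(result.best.a0 + result.best.a1 * hrf.values)


def sweep_fit(
    pair: ODPair,
    paradigm: StimulusTrain,
    dpf_values,
    which: str,
    fixed_other_dpf: float,
    fs: float,
    label: str = "",
    case: str = "",
    **fit_kwargs,
) -> pd.DataFrame:
    """One fit per swept DPF value, with the other wavelength's DPF fixed.

    ``which`` selects the swept wavelength ("l1" or "l2").  Rows carry
    the HRF attributes of the fitted activity curve; a row whose fit
    raises is kept with the error message and NaN attributes, and the
    sweep continues.
    """
    if which not in ("l1", "l2"):
        raise ValueError("which must be 'l1' or 'l2'")
    rows = []
    for dpf in dpf_values:
        dpf = float(dpf)
        dpf_l1, dpf_l2 = (dpf, fixed_other_dpf) if which == "l1" else (fixed_other_dpf, dpf)
        row: dict = {"label": label, "case": case, "dpf_l1": dpf_l1, "dpf_l2": dpf_l2}
        try:
            result = fit(pair, paradigm, dpf_l1, dpf_l2, fs, **fit_kwargs)
            curve = fitted_activity_curve(result, paradigm, fs)
            attrs = extract_attributes(curve, paradigm.task_window)
            row.update(attrs.as_dict())
            row.update({"j2": result.j2, "converged": result.converged, "error": ""})
        except Exception as exc:  # noqa: BLE001 - per-row failures must not kill the sweep
            row.update({name: np.nan for name in HRFAttributes.FIELDS})
            row.update({"j2": np.nan, "converged": False, "error": str(exc)})
        rows.append(row)
    return pd.DataFrame(rows)[list(SWEEP_COLUMNS)]
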