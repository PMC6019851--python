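"""Modified Beer-Lambert law (MBLL) conversions.

Light attenuation through tissue is summarised as optical density
``OD = ln(I_in / I_out)``.  For small concentration changes the MBLL
makes the optical-density change at wavelength ``λj`` linear in the
chromophore changes:

    ΔOD_λj = (ε_HbO,λj ΔHbO + ε_HbR,λj ΔHbR) · d · DPF_λj,

with extinction coefficients ``ε``, source-detector separation ``d``
and differential path-length factor ``DPF``.  The geometric scattering
term is constant in time and cancels in ΔOD, so it is carried on the
coefficient object only for documentation.  With two wavelengths the
relation is a 2x2 linear system solved per sample.

Alongside the generic system this module carries the fixed-coefficient
HbO reconstruction used throughout the DPF sensitivity analysis for the
760/830 nm pair:

    y_HbO(k) = 0.2170 ΔOD_λ2(k)/DPF_λ2 - 0.1015 ΔOD_λ1(k)/DPF_λ1.

The constants 0.2170 and 0.1015 are printed values for that wavelength
pair; the extinction table behind them is not public, so they are kept
as named constants rather than recomputed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import TimeSeries, require_same_grid

__all__ = [
    "MBLLCoefficients",
    "ODPair",
    "optical_density",
    "forward_od",
    "invert_od",
    "reconstruct_hbo_paper",
    "HBO_COEF_L1",
    "HBO_COEF_L2",
]

#: Fixed coefficients of the HbO reconstruction for the 760/830 nm pair.
#: HBO_COEF_L2 multiplies ΔOD at λ2 = 830 nm, HBO_COEF_L1 the (subtracted)
#: ΔOD at λ1 = 760 nm.
HBO_COEF_L2 = 0.2170
HBO_COEF_L1 = 0.1015


@dataclass(frozen=True)
class MBLLCoefficients:
    """Extinction coefficients and geometry of a two-wavelength channel.

    Extinction coefficients are per (concentration unit x cm); the
    scattering offset G(λ) is constant and cancels in ΔOD — it is never
    estimated.
    """

    eps_hbo_l1: float
    eps_hbr_l1: float
    eps_hbo_l2: float
    eps_hbr_l2: float
    separation_cm: float = 1.0
    scattering_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.separation_cm <= 0:
            raise ValueError("source-detector separation must be positive")
        if abs(self.determinant) < 1e-12:
            raise ValueError(
                "extinction matrix is singular (determinant "
                f"{self.determinant:.3e}); the two wavelengths do not separate HbO/HbR"
            )

    @property
    def determinant(self) -> float:
        """``ε_HbR,λ1 ε_HbO,λ2 - ε_HbR,λ2 ε_HbO,λ1`` of the 2x2 system."""
        return self.eps_hbr_l1 * self.eps_hbo_l2 - self.eps_hbr_l2 * self.eps_hbo_l1


@dataclass
class ODPair:
    """Paired optical-density series with the DPFs used to interpret them."""

    od_l1: TimeSeries
    od_l2: TimeSeries
    dpf_l1: float
    dpf_l2: float
    coefficients: MBLLCoefficients | None = None

    def __post_init__(self) -> None:
        require_same_grid(self.od_l1, self.od_l2, "optical-density series")
        _check_dpfs(self.dpf_l1, self.dpf_l2)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"time_s": self.od_l1.times, "od_l1": self.od_l1.values, "od_l2": self.od_l2.values}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, dpf_l1: float, dpf_l2: float, coefficients=None) -> "ODPair":
        import pandas as pd

        frame = pd.read_csv(path)
        od1 = TimeSeries.from_frame(frame, value_column="od_l1")
        od2 = TimeSeries.from_frame(frame, value_column="od_l2")
        return cls(od1, od2, dpf_l1, dpf_l2, coefficients)


def _check_dpfs(dpf_l1: float, dpf_l2: float) -> None:
    if dpf_l1 <= 0 or dpf_l2 <= 0:
        raise ValueError(f"DPFs must be positive, got ({dpf_l1}, {dpf_l2})")


def optical_density(incident: float, detected: float) -> float:
    """Optical density ``ln(I_in / I_out)`` of one intensity reading."""
    if incident <= 0 or detected <= 0:
        raise ValueError("light intensities must be positive")
    return math.log(incident / detected)


def forward_od(
    delta_hbo: TimeSeries,
    delta_hbr: TimeSeries,
    coefficients: MBLLCoefficients,
    dpf_l1: float,
    dpf_l2: float,
) -> ODPair:
    """Map chromophore changes to the optical densities they produce."""
    require_same_grid(delta_hbo, delta_hbr, "chromophore series")
    _check_dpfs(dpf_l1, dpf_l2)
    c, d = coefficients, coefficients.separation_cm
    od1 = (c.eps_hbo_l1 * delta_hbo.values + c.eps_hbr_l1 * delta_hbr.values) * d * dpf_l1
    od2 = (c.eps_hbo_l2 * delta_hbo.values + c.eps_hbr_l2 * delta_hbr.values) * d * dpf_l2
    return ODPair(delta_hbo.copy_with(od1), delta_hbo.copy_with(od2), dpf_l1, dpf_l2, c)


def invert_od(pair: ODPair) -> tuple[TimeSeries, TimeSeries]:
    """Recover (ΔHbO, ΔHbR) from a two-wavelength OD pair.

    Each OD series is first normalised by its path length
    (``d · DPF_λj``), then the 2x2 extinction system is inverted per
    sample:

        ΔHbO = (ε_HbR,λ1 ΔOD'_λ2 - ε_HbR,λ2 ΔOD'_λ1) / det
        ΔHbR = (ε_HbO,λ2 ΔOD'_λ1 - ε_HbO,λ1 ΔOD'_λ2) / det
    """
    c = pair.coefficients
    if c is None:
        raise ValueError("ODPair carries no extinction coefficients to invert with")
    det = c.determinant
    if abs(det) < 1e-12:
        raise ValueError(
            f"extinction matrix nearly singular (det={det:.3e}); inversion ill-conditioned"
        )
    od1 = pair.od_l1.values / (pair.dpf_l1 * c.separation_cm)
    od2 = pair.od_l2.values / (pair.dpf_l2 * c.separation_cm)
    hbo = (c.eps_hbr_l1 * od2 - c.eps_hbr_l2 * od1) / det
    hbr = (c.eps_hbo_l2 * od1 - c.eps_hbo_l1 * od2) / det
    return pair.od_l1.copy_with(hbo), pair.od_l1.copy_with(hbr)


def reconstruct_hbo_paper(
    od_l1: TimeSeries,
    od_l2: TimeSeries,
    dpf_l1: float,
    dpf_l2: float,
) -> TimeSeries:
    """Fixed-coefficient HbO reconstruction for the 760/830 nm pair.

    ``y(k) = 0.2170 od_l2(k)/dpf_l2 - 0.1015 od_l1(k)/dpf_l1``.

    Output units follow the constants ("paper units", not molar).  The
    value increases with ``dpf_l1`` wherever ``od_l1 > 0`` and decreases
    with ``dpf_l2`` wherever ``od_l2 > 0`` — the mechanism behind the
    DPF sensitivity of the reconstructed response.
    """
    require_same_grid(od_l1, od_l2, "optical-density series")
    _check_dpfs(dpf_l1, dpf_l2)
    y = HBO_COEF_L2 * od_l2.values / dpf_l2 - HBO_COEF_L1 * od_l1.values / dpf_l1
    return od_l1.copy_with(y)
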