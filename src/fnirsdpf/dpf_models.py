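"""Differential path-length factor (DPF) models.

The DPF is the dimensionless factor by which the mean photon path in
tissue exceeds the source-detector separation on the scalp.  Two
empirical models are exposed:

* four wavelength-specific age regressions calibrated at 690, 744, 807
  and 832 nm, each of the form ``intercept + slope * age**exponent``;
* a joint age-wavelength surface valid across the near-infrared window,
  cubic in wavelength and power-law in age.

Both are regression fits from the time-of-flight literature; neither is
derived from tissue optics here.  They are kept separate and are never
silently substituted for one another: the calibrated regressions answer
queries at exactly their four wavelengths, the surface answers any
wavelength in the NIR window.
"""

from __future__ import annotations

__all__ = [
    "CALIBRATED_WAVELENGTHS_NM",
    "dpf_at_calibrated_wavelength",
    "dpf_general",
]

# (intercept, slope, age exponent) of the per-wavelength age regressions.
_CALIBRATED: dict[int, tuple[float, float, float]] = {
    690: (5.38, 0.049, 0.877),
    744: (5.11, 0.106, 0.723),
    807: (4.99, 0.067, 0.814),
    832: (4.67, 0.062, 0.819),
}

CALIBRATED_WAVELENGTHS_NM: tuple[int, ...] = tuple(sorted(_CALIBRATED))

# Validity window of the general surface: the NIR window used by fNIRS
# instruments.  The cubic wavelength term makes extrapolation unsafe, so
# queries outside are rejected rather than evaluated.
GENERAL_WAVELENGTH_RANGE_NM = (650.0, 900.0)
GENERAL_AGE_RANGE_YEARS = (0.0, 100.0)


def _check_age(age_years: float) -> float:
    age = float(age_years)
    if not age >= 0.0:
        raise ValueError(f"age must be non-negative, got {age_years}")
    return age


def dpf_at_calibrated_wavelength(wavelength_nm: float, age_years: float) -> float:
    """DPF from the age regression calibrated at one of four wavelengths.

    Parameters
    ----------
    wavelength_nm : {690, 744, 807, 832}
        Wavelength channel; must be exactly one of the four calibrated
        values.
    age_years : float
        Subject age in years (fractional ages allowed, ``>= 0``).

    Returns
    -------
    float
        Dimensionless DPF, ``intercept + slope * age**exponent``.
    """
    age = _check_age(age_years)
    key = int(wavelength_nm)
    if key != wavelength_nm or key not in _CALIBRATED:
        raise ValueError(
            f"no calibrated DPF regression at {wavelength_nm} nm; "
            f"supported wavelengths are {CALIBRATED_WAVELENGTHS_NM} nm"
        )
    intercept, slope, exponent = _CALIBRATED[key]
    return intercept + slope * age**exponent


def dpf_general(wavelength_nm: float, age_years: float) -> float:
    """DPF from the joint age-wavelength surface.

    ``dpf = 223.3 + 0.05624 A^0.8493 - 5.723e-7 λ^3 + 0.001245 λ^2 - 0.9025 λ``
    with age ``A`` in years and wavelength ``λ`` in nm.

    Valid for ``λ`` in [650, 900] nm and ``A`` in [0, 100] years;
    queries outside are rejected.
    """
    age = _check_age(age_years)
    lam = float(wavelength_nm)
    lo, hi = GENERAL_WAVELENGTH_RANGE_NM
    if not (lo <= lam <= hi):
        raise ValueError(
            f"wavelength {wavelength_nm} nm outside the supported NIR window "
            f"[{lo:.0f}, {hi:.0f}] nm"
        )
    if age > GENERAL_AGE_RANGE_YEARS[1]:
        raise ValueError(
            f"age {age_years} y outside the supported range "
            f"[0, {GENERAL_AGE_RANGE_YEARS[1]:.0f}] y"
        )
    return (
        223.3
        + 0.05624 * age**0.8493
        - 5.723e-7 * lam**3
        + 0.001245 * lam**2
        - 0.9025 * lam
    )
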