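# fnirsdpf

Sensitivity analysis of the fNIRS hemodynamic response to the
differential path-length factor (DPF).

## The problem

Continuous-wave functional near-infrared spectroscopy (fNIRS) measures
optical-density changes ΔOD at two wavelengths (typically 760 and
830 nm) and converts them to oxy-/deoxy-hemoglobin concentration
changes with the modified Beer-Lambert law (MBLL):

    ΔOD_λ = (ε_HbO,λ ΔHbO + ε_HbR,λ ΔHbR) · d · DPF_λ

The DPF — how many times farther than the source-detector separation
`d` the scattered photons actually travel — cannot be measured by CW
instruments and is usually assumed, with conventional values between 3
and 8. This package quantifies what that assumption does to the
hemodynamic response function (HRF): its peak, time to peak, full
width at half maximum (FWHM) and post-stimulus undershoot.

It is aimed at fNIRS methodologists and BCI researchers who want to
know how much of an HRF "feature" is physiology and how much is a DPF
choice.

## What it computes

* **DPF models** (`dpf_models`): the four calibrated age regressions
  `DPF_λ = b0 + b1·A^b2` at 690/744/807/832 nm, and the general
  age-wavelength surface valid over the 650-900 nm NIR window.
* **Hemodynamics** (`hemodynamics`): the canonical double-gamma kernel
  `h(t) = g(t; α1, β1) − g(t; α2, β2)/6`, stimulus boxcar convolution
  `HRF = h * u`, and HRF attribute extraction.
* **MBLL** (`mbll`): intensity → ΔOD, the generic two-wavelength
  forward/inverse conversion, and the fixed-coefficient HbO
  reconstruction `y = 0.2170·ΔOD_λ2/DPF_λ2 − 0.1015·ΔOD_λ1/DPF_λ1`.
* **Synthetic data** (`synthetic_data`): the optical signal model
  `y = a0 + a1·HRF + ac sin(2πfc t) + ar sin(2πfr t) + am sin(2πfm t) + ε`
  under the block-design paradigms, generated at 1.81 Hz and resampled
  to 100 Hz.
* **OD split** (`od_split`): the sign-constrained decomposition of a
  simulated HbO series into two optical densities minimising
  `J1 = Σ (y − 0.0375·ΔOD_λ2 + 0.01644·ΔOD_λ1)²` under the four sign
  cases, via a closed-form minimum-norm solution.
* **HRF fit** (`hrf_fit`): the twelve-parameter estimation problem
  `min J2(α1, α2, β1, β2, a0, a1, ac, ar, am, fc, fr, fm)` under the
  physiological box constraints C1-C12, solved by multi-start
  Nelder-Mead in a logistic box bijection.
* **Pipeline** (`pipeline`, `cli`): simulation and fit studies sweeping
  DPF over 3-8 for each wavelength, emitting attribute tables and a
  reproducibility manifest.

## Worked example

```python
import fnirsdpf as f

paradigm = f.simulated_paradigm(10, "St1")          # 10 s rest / 10 s task / 30 s rest
hrf = f.HRFParams()                                  # canonical (6, 16, 1, 1)
nuisance = f.NuisanceParams(a0=3.0, a1=5.0, noise_sd=0.1)
raw = f.generate_signal(hrf, nuisance, paradigm, fs=1.81, seed=42)
signal = f.resample_to(raw, 100.0)

result = f.split_signal(signal, "case1")             # both ODs constrained >= 0
for dpf2 in (3.0, f.TRUE_DPF_L2, 8.0):
    rec = f.reconstruct_under_dpf(result, f.TRUE_DPF_L1, dpf2)
    attrs = f.extract_attributes(rec, paradigm.task_window)
    print(f"DPF_l2={dpf2:5.3f}: peak={attrs.peak_value:6.3f}  "
          f"undershoot={attrs.undershoot_depth:5.3f}")
```

prints

```
DPF_l2=3.000: peak=15.057  undershoot=1.352
DPF_l2=5.787: peak= 7.806  undershoot=0.701
DPF_l2=8.000: peak= 5.646  undershoot=0.507
```

At the implied true value DPF_λ2 ≈ 5.787 the reconstruction returns
the simulated signal exactly (peak 7.8 = baseline 3 + response); an
underestimated DPF_λ2 roughly doubles the apparent peak and
undershoot, an overestimated one shrinks them — the core sensitivity
result. The same machinery is available from the shell:

```
fnirsdpf simulate --task-s 10 --pattern St1 --seed 42 --out signal.csv
fnirsdpf split --case case1 --in signal.csv --out odpair.csv --report report.json
fnirsdpf run --mode simulation --out-dir runs/sim
```

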