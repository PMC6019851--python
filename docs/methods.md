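# Methods

This note documents the models, the numerical choices and the defaults
behind `fnirsdpf`, and what the synthetic experiments do and do not
show about real recordings.

## Signal model

One fNIRS channel's observed HbO series is modelled as

    y(t) = a0 + a1·HRF(t) + ac·sin(2π fc t) + ar·sin(2π fr t)
         + am·sin(2π fm t) + ε(t),     ε ~ N(0, σ²) i.i.d.

with time in seconds. `HRF = h * u` is the double-gamma canonical
kernel convolved with the paradigm's unit boxcar `u`:

    h(t) = t^(α1−1) β1^α1 e^(−β1 t) / Γ(α1)
         − t^(α2−1) β2^α2 e^(−β2 t) / (6 Γ(α2))

The divisor 6 of the undershoot term is part of the canonical form and
is never estimated. The three sinusoids stand in for cardiac (~1 Hz),
respiratory (~0.25 Hz) and Mayer-wave (~0.1 Hz) interference; they
have zero phase by construction. The model has no drift, motion or
heart-rate-variability terms — structured artifacts of real data are
deliberately out of scope.

Defaults: canonical shape (α1, α2, β1, β2) = (6, 16, 1, 1), giving a
peak 5 s after an impulse; kernel truncated at 32 s where the response
has settled to well below 1 % of peak; analysis grid dt = 0.01 s
(100 Hz); acquisition rate 1.81 Hz; noise σ = 0.1 signal units (not
fixed by the protocol; chosen as a visible-but-small perturbation, and
set to 0 in recovery experiments).

A generated sinusoid must satisfy fs > 2f, so the 1.81 Hz acquisition
grid cannot carry a cardiac band. The simulation arm therefore
generates HRF + baseline + noise at 1.81 Hz and resamples (the
protocol's route), while fit-study data with full nuisance terms are
synthesised directly at 100 Hz. Resampling is linear interpolation:
exact on piecewise-linear signals, deterministic, and free of the
ringing a band-limited method would add to boxcar-driven signals.

## Paradigms

* Real-protocol block design: 15 s rest, then four trials of 15 s task
  + 15 s rest (onsets 15/45/75/105 s, 135 s total).
* Simulation paradigms: 10 s initial rest, a stimulus train of
  10/20/30 s blocks, 30 s terminal rest. The five trains St1-St5 are
  not fixed numerically by the protocol, so they are explicit,
  overridable configuration: St1 one block; St2 two blocks, 20 s gap;
  St3 three blocks, 15 s gaps; St4 two blocks, 10 s gap; St5 a full
  block then a half-duration block, 15 s gap.

## DPF models

Calibrated age regressions `b0 + b1·A^b2` at 690/744/807/832 nm
(intercepts 5.38, 5.11, 4.99, 4.67) and the joint surface

    DPF(λ, A) = 223.3 + 0.05624 A^0.8493 − 5.723e−7 λ³
              + 0.001245 λ² − 0.9025 λ.

Both are exposed; neither is substituted for the other, since their
relation at the calibrated wavelengths is not defined by the sources
of the coefficients. The surface is restricted to λ ∈ [650, 900] nm
and A ∈ [0, 100] y — a cubic in λ extrapolates unsafely, so
out-of-window queries are rejected rather than answered.

## Optical-density split (J1)

For a simulated HbO series the per-sample constraint

    0.0375·ΔOD_λ2 − 0.01644·ΔOD_λ1 = y(k)

is one equation in two unknowns. Restricted to a sign quadrant
(case 1 (+,+), case 2 (−,−), case 3 (+,−), case 4 (−,+)), the adopted
solution is the minimum-norm point of the line-quadrant intersection:
the orthogonal projection of the origin when admissible, else the
smaller-norm axis point. This is deterministic, has a closed form,
and attains the smallest possible J1; a brute-force refined grid
search over the quadrant validates it in the tests. Signs are
enforced non-strictly so the origin is always admissible. A positive
sample under case 3 (or negative under case 4) is unreachable — the
nearest quadrant point to the line is the origin — so the sample is
counted infeasible and contributes y(k)² to J1. Consequently case 3
reproduces exactly the non-positive part of a signal and case 4 the
non-negative part.

Dividing the reconstruction constants by the J1 constants gives the
implied true DPFs, 0.1015/0.01644 ≈ 6.174 (λ1) and 0.2170/0.0375 ≈
5.787 (λ2), exposed as `TRUE_DPF_L1`/`TRUE_DPF_L2`; reconstructing at
those values inverts the split on feasible samples, and sweeping them
over 3-8 is the sensitivity experiment. The reconstruction
coefficients 0.2170/0.1015 are carried as named constants: the
extinction table they derive from is not public, so recomputing them
from any particular published table would silently change the
quantity under study.

## Twelve-parameter fit (J2)

The fit minimises the squared error between the signal model
(noise-free) and the HbO series reconstructed from a measured OD pair
at a given DPF pair, over the box

    α1∈[2,10], α2∈[6,20], β1∈[0.5,2], β2∈[0,1.5], a0∈[0,20],
    a1∈[0,15], ac,ar,am∈[0,2], fc∈[0.5,1.5], fr∈[0.2,0.3], fm∈[0.09,0.1].

The coefficient-wavelength pairing of the target follows the
reconstruction relation (0.2170 with λ2, 0.1015 with λ1) throughout.

Bound handling: Nelder-Mead is unconstrained, so the search runs in
z-space with `x = lo + (hi − lo)·expit(z)` per coordinate — smooth,
interior-only, and guaranteeing in-box results by construction
(preferred over penalty terms, which distort the landscape near the
bounds and need a tuned weight).

Search strategy: the cost is strongly multimodal in the sinusoid
frequencies — local minima spaced roughly 1/T apart (T the record
length), which a simplex cannot cross. Plain uniform multi-start
Nelder-Mead was measured to leave the respiratory frequency ~0.04 Hz
off even with 20 restarts. The estimator therefore runs (i)
`n_restarts` = 5 short simplex probes (max_iter/3 iterations each)
from seeded uniform in-box points, then (ii) for the 2 best probes,
2 rounds of frequency reseeding — a 161-point one-dimensional scan of
each frequency over its box with the other eleven parameters held
fixed, jumping to the best grid point — each followed by a full
simplex run (standard 1/2/0.5/0.5 coefficients, initial simplex edge
0.5 in z-space, max_iter = 1500, fatol = 1e−10). All randomness comes
from one seeded generator, so results are bit-reproducible. On
noise-free in-box datasets this recovers the activity strength with
median relative error well under 1 % and the three frequencies to
~1e−5 Hz in about 8 s per fit (single core); occasional restarts end
in an HRF-shape/amplitude trade-off valley, which the multi-dataset
medians in the tests are designed to tolerate.

## HRF attributes

Baseline = mean over the pre-onset rest. Peak = first global maximum
in [task onset, offset + 10 s] (the pad catches delayed peaks; the
analysis protocol does not define these windows, so they are fixed
here and recorded). Time-to-peak is measured from task onset. FWHM is
measured above baseline, with half-maximum crossings located by
linear interpolation between bracketing samples and ties at the
maximum broken by earliest time; it is NaN when the curve never rises
above baseline. Undershoot depth = max(0, baseline − minimum) over
(task offset, end of series].

## Synthetic subjects for the fit study

Real recordings for the six-subject arm are not available, so the fit
study runs on synthetic subjects: seeded draws of HRF shape near
canonical, baseline, activity strength and nuisance terms, all inside
the constraint box with amplitudes bounded away from zero (a zero
amplitude makes its frequency unidentifiable and recovery
meaningless). Each subject's OD pair is constructed to be strictly
positive — `od_l1` an offset plus a concave monotone companion of the
signal, `od_l2` chosen so the reconstruction at the implied true DPFs
returns the signal exactly. Positive ODs put the subject in the
regime where the reconstructed and fitted HRF peak rises with DPF_λ1
and falls with DPF_λ2, and the concave companion makes the FWHM move
with the DPFs in opposite directions between the two wavelengths —
the qualitative signature reported for real recordings. Passing these
checks shows the machinery propagates DPF errors with the right
directions and magnitudes under the stated model; it does not certify
behaviour under real-data artifacts (motion, drift, non-sinusoidal
physiology) that the model excludes.

Problem sizes: the recovery and direction experiments use the
shortest paradigm (St1, 10 s task, 50 s record at 100 Hz), 25 datasets
for recovery medians and 6 DPF values per sweep; the simulation-study
driver defaults to the full 5 trains x 3 durations x 4 cases grid.

## Known limitations

* The split's minimum-norm rule is one canonical selection among the
  infinitely many J1-optimal splits; other selection rules would give
  different (equally J1-optimal) OD pairs and different sweep curves.
* Attribute extraction assumes a single dominant response per task
  window; overlapping responses from closely spaced blocks are
  summarised by their global maximum only.
* The fit's frequency reseeding assumes the three nuisance bands do
  not overlap (true of the constraint box).
* Output concentration units follow the fixed reconstruction
  coefficients ("paper units"), not molar units.
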