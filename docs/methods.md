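# Methods

This note records the model, the numerical choices, and the limits of
what the simulation-based tests demonstrate.

## Signal model

The chain is simulated at complex baseband. The transmitted CW tone is
synthesised as a unit cos/sin pair at the intermediate frequency f_IF;
up- and down-conversion move its spectrum to and from the effective RF
f_rf = f_c − f_IF, so all physics depends on f_rf only. After mixing
the return against the transmit reference and low-pass filtering, the
receiver holds

    I(t) = (A/2)·cos(φ(t) + Δθ(t)) + dc_I + n_I(t)
    Q(t) = (A/2)·sin(φ(t) + Δθ(t)) + dc_Q + n_Q(t)
    φ(t) = −4π f_rf (d₀ + x(t)) / c

with A a single scalar attenuation (radar cross-section and path loss
are not modelled separately), Δθ the residual transmit phase noise,
dc the branch offsets and n additive noise. `simulate_baseband`
produces this closed form directly: sampling a GHz carrier to re-derive
it numerically would add cost and rounding error but no information.
The explicit chain — delay, homodyne mixing, 8th-order Butterworth
low-pass, decimation — exists as `simulate_baseband_mixing` and is
checked against the closed form in the tests on a scaled-down link
(f_rf = 200 Hz) where the carrier is representable; agreement is at the
level of the filter's passband ripple (≲0.5% of the envelope).

Demodulation inverts the phase with the four-quadrant arctangent plus
temporal unwrapping (threshold π; a tie at exactly π is left as
no-jump, numpy's convention). The printed two-quadrant arctan form
fails whenever φ leaves (−π/2, π/2), which happens for any d₀ away
from the first optimum point or any motion crossing a quadrant
boundary; continuous phase tracking of the rotating baseband vector is
the behaviour the geometry implies, and it is what makes recovery
independent of d₀ — verified pairwise to 1e-9 m over
d₀ ∈ {0, λ/8, λ/4, 3λ/8, λ/2}.

## Parameters and defaults

| parameter | default | why |
|---|---|---|
| f_c, f_IF | 2.02 GHz, 20 MHz | effective RF 2.0 GHz, near the top of a typical low-cost SDR transceiver's 50 MHz–2.2 GHz range, where phase-per-millimetre sensitivity is highest; the f_c/f_IF split is physically free, f_IF ≈ f_c/100 |
| sample rate | 100 Hz | baseband; two decades above the breathing band |
| A | 1 | demodulation is scale-invariant, so attenuation only matters relative to additive noise |
| d₀ | λ/8 (first optimum point) | lets the same configuration exercise the single-channel reference path; the quadrature path is d₀-independent |
| Δθ | 0 | shared PLL reference makes transmit phase noise common-mode between I and Q, where atan2 cancels it |
| breathing regimes | 0.5 Hz / 3 mm; 1.2 Hz + 0.05 Hz drift of 1.5 mm amplitude; breathe/apnea schedules | the three study conditions: normal, accelerated (with body-movement drift below the 0.1 Hz band edge), interrupted |
| record length | 60 s | makes 0.5 Hz and 1.2 Hz exact DFT bins (Δf = 1/60 Hz) |
| moving average | 0.25 s, odd sample count, shrinking edge windows | smooths additive noise (variance ÷ ~25) while attenuating a 0.5 Hz component by only ~2.5% |
| analysis band | 0.1–3 Hz | covers both breathing regimes, excludes DC and sub-0.1 Hz drift |
| spectral window / padding | Hann, zero-pad to exactly 4× record length | see below |
| peak-to-peak estimator | quantile(1−q) − quantile(q); q = 0 raw, q = 0.05 in the robust default | raw max−min is exact on clean data; the trimmed version resists noise-extreme inflation at the cost of ~1% bias on a sinusoid |
| apnea detector | 4 s sliding-window excursion < 1 mm | window ≈ two breathing periods; threshold is a user parameter with no physiological calibration claimed |

## Numerical choices

* **Spectral padding.** The padded transform length is an integer
  multiple (4×) of the record length, not the next power of two. Only
  an integer multiple keeps the original DFT bins on the padded grid;
  with a Hann window the mainlobe peak of an exact-bin sinusoid then
  falls exactly on its true bin, so exact-bin breathing rates are
  recovered with zero error rather than to within half a padded bin.
  numpy's mixed-radix FFT handles 4N-length transforms efficiently.
* **Magnitude normalisation.** Spectra are scaled so a unit-amplitude
  exact-bin sinusoid reads 1.0, making peak heights directly
  interpretable as displacement amplitudes.
* **Dominant-frequency ties** break toward the lower frequency
  (argmax returns the first maximum on an ascending grid).
* **DC-offset estimation** uses the algebraic (Kåsa) circle fit: with
  offset-free noise the baseband samples lie on a circle of radius A/2,
  and the fit is a single linear least-squares solve — deterministic
  and test-friendly. The fit degenerates as the arc flattens; when the
  minor/major extent ratio of the (I,Q) cloud falls below 1e-2
  (roughly a 0.08 rad arc) the function warns and returns zero offsets
  rather than an unstable centre. Offset correction is off by default
  because the simulator's default baseband is offset-free.
* **Geometry constraints.** d₀ ≥ λ and motion amplitude ≥ λ produce
  warnings, not errors: once the phase is unwrapped the demodulated
  oscillation is invariant to d₀ modulo λ/2, and the constraint only
  matters for interpreting the absolute range, which the analysis layer
  never uses. The raw unwrapped x̄ = d₀ + x(t) is available behind
  `remove_mean=False` with exactly that stated ambiguity.
* **Apnea continuity.** Apnea segments hold the last breathing
  displacement (the sinusoid's phase clock freezes) instead of snapping
  to zero — a chest does not teleport, and step edges would leak
  spectral energy across the analysis band.

## What the generator emulates — and what it does not

The motion generator produces noise-free deterministic kinematics:
pure sinusoids, a sinusoidal drift, phase-continuous pauses, plus
optional seeded white jitter. Real chest motion has asymmetric
inhale/exhale shapes, amplitude and rate variability, heartbeat
superposition, and posture changes; none of these are modelled, and no
heartbeat-band analysis is attempted. Passing tests therefore
demonstrate the correctness of the *signal chain* — geometry, phase
modulation, demodulation, spectral estimation, segmentation — under
the stated study conditions, not clinical performance on human data.
Real-radar impairments beyond the noise model (ADC quantisation,
finite transceiver bandwidth and dynamic range, antenna patterns,
clutter and multipath) are likewise out of scope.

## Problem sizes

Every end-to-end experiment uses 60 s records at 100 Hz (6000 samples);
the round-trip oracle uses 100 random 10 s motions and the noise study
100 seeded 60 s runs at 20 dB SNR. These sizes make every quantity of
interest an exact DFT bin and keep the whole suite and the acceptance
script in the low seconds on one CPU.

## Known limitations

* Absolute range is reported only modulo λ/2 by construction.
* The accelerated regime's rate is reported as 60·f of the spectral
  peak (1.2 Hz → 72 breaths/min); no independent breath-counting
  estimator is provided.
* The additive-noise model is white and branch-independent; correlated
  or 1/f receiver noise is not modelled.
* The apnea threshold (1 mm default) is a user parameter, not a
  clinically validated criterion.
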