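# breathradar

A software-defined continuous-wave (CW) Doppler radar signal chain for
non-contact respiration monitoring, implemented entirely in software.
The package simulates quadrature baseband returns from a breathing
chest, recovers the displacement waveform by arctangent demodulation,
and estimates the breathing rate, the peak-to-peak abdominal shift, and
apnea (interrupted-breathing) episodes. A single-channel reference path
is included to demonstrate the null-detection-point failure that the
quadrature design eliminates.

It is aimed at researchers and students in biomedical radar sensing who
want a reproducible, hardware-free testbed for the CW Doppler
vital-sign chain: every stage that a software-defined radio transceiver
would perform — waveform synthesis, mixing, filtering, demodulation,
spectral analysis — is a plain, testable Python function.

## The model

A CW radar transmits at an effective RF frequency f_rf = f_c − f_IF
(carrier minus intermediate frequency, wavelength λ = c/f_rf). The
return from a chest at nominal distance d₀ oscillating with
displacement x(t) is delayed by the round trip τ(t) = 2(d₀ + x(t))/c.
After quadrature down-conversion and low-pass filtering the baseband
pair is

    I(t) = (A/2)·cos φ(t),   Q(t) = (A/2)·sin φ(t),
    φ(t) = −4π f_rf (d₀ + x(t)) / c,

where A is a scalar attenuation. The displacement is recovered with the
four-quadrant arctangent and temporal unwrapping:

    x̄(t) = d₀ + x(t) = −atan2(Q, I) · c / (4π f_rf).

Because atan2 uses both channels, recovery is independent of d₀. A
single-channel receiver (I only) is insensitive to small motion at the
null distances d₀ = λ(1/4 + k/4) — there cos φ is at an extremum and
motion enters only at second order — while it works best at the optimum
distances d₀ = λ(1/8 + k/4). The package verifies both behaviours by
simulation.

With a shared phase-locked-loop reference the transmit phase noise is
common to both branches and cancels from atan2(Q, I); the noise model
therefore defaults to zero residual phase noise, with additive white
noise, correlated phase noise, and DC offsets available as options.

## Worked example

Run the default pipeline (normal breathing: 0.5 Hz, 3 mm peak-to-peak,
60 s at 100 Hz, effective RF 2.0 GHz, target at the first optimum point
λ/8 ≈ 1.9 cm, no noise):

```sh
$ breathradar run -o out/
dominant frequency : 0.5 Hz
breathing rate     : 30 breaths/min
peak-to-peak shift : 2.89 mm (raw 3 mm)
apnea episodes     : none
```

The chain recovered the simulated 0.5 Hz oscillation exactly (the 60 s
record makes 0.5 Hz an exact DFT bin) and converted it to 30
breaths/min. The raw max-minus-min of the demodulated displacement is
the simulated 3 mm abdominal shift; the headline 2.89 mm figure is the
deliberately conservative robust estimate (0.25 s moving average plus
5%/95% quantiles), which shaves a few percent off a clean sinusoid in
exchange for stability under noise.

An interrupted-breathing run (20 s breathing, 10 s pause, 20 s
breathing) localises the pause:

```sh
$ breathradar run -o out/ -O motion.regime=interrupted
...
apnea episodes     : [21.8 s, 28.2 s)
```

The detected interval sits inside the true 20–30 s pause; its edges are
pulled inward by the 4 s sliding excursion window, i.e. the boundary
error is bounded by the window length.

The same stages are available as separate `simulate`, `demodulate` and
`analyze` subcommands operating on CSV (or raw interleaved float32 I/Q
with a JSON sidecar) files, and as library functions
(`breathradar.run_pipeline`, see `docs/methods.md`). Every run writes a
JSON manifest with the configuration hash, seed and stage timings, and
identical configuration + seed reproduce all outputs byte for byte.

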