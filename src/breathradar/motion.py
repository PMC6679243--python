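"""Synthetic chest-displacement generators.

Three regimes mirror the experimental conditions a desk-scale breathing
study exercises:

* **normal** — regular sinusoidal abdominal motion, millimetre scale,
  around 0.5 Hz (30 breaths/min);
* **accelerated** — faster oscillation (e.g. 1.2 Hz) superposed with a
  slow sub-0.1 Hz body-movement drift;
* **interrupted** — alternating breathing and flat (apnea) segments,
  continuous at the joins.

Generated traces are the simulation ground truth against which the
demodulated output of the full radar chain is judged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .exceptions import AliasingError, EmptyScheduleError


@dataclass(frozen=True)
class MotionSignal:
    """Uniformly sampled chest displacement x(t), in metres about d0.

    ``samples`` is zero-referenced displacement (the nominal distance
    lives in the propagation channel, not here).
    """

    samples: np.ndarray
    sample_rate_hz: float
    regime: str = "custom"

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "samples", np.asarray(self.samples, dtype=float)
        )
        if self.samples.ndim != 1:
            raise ValueError("motion samples must be one-dimensional")
        if not self.sample_rate_hz > 0:
            raise ValueError("sample rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("motion samples must be finite")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz

    def time_s(self) -> np.ndarray:
        """Sample times from record start, seconds."""
        return np.arange(self.n_samples) / self.sample_rate_hz


def _n_samples(duration_s: float, sample_rate_hz: float) -> int:
    n = int(round(duration_s * sample_rate_hz))
    if n <= 0:
        raise ValueError("duration and sample rate must give >= 1 sample")
    return n


def _check_rate(rate_hz: float, sample_rate_hz: float) -> None:
    if rate_hz < 0:
        raise ValueError("breathing rate must be non-negative")
    if rate_hz > 0 and sample_rate_hz <= 2.0 * rate_hz:
        raise AliasingError(
            f"sample rate {sample_rate_hz} Hz cannot resolve a "
            f"{rate_hz} Hz oscillation (need fs > 2*rate)"
        )


def _jitter(n: int, std_m: float, seed) -> np.ndarray:
    if std_m == 0.0:
        return np.zeros(n)
    rng = np.random.default_rng(seed)
    return rng.normal(0.0, std_m, n)


def normal_breathing(
    rate_hz: float = 0.5,
    peak_to_peak_m: float = 3e-3,
    duration_s: float = 60.0,
    sample_rate_hz: float = 100.0,
    jitter_std_m: float = 0.0,
    seed: int | None = None,
) -> MotionSignal:
    """Regular breathing: a pure sinusoid.

    x(t) = (peak_to_peak/2) * sin(2*pi*rate*t), zero mean. Defaults are
    the normal-breath condition: 0.5 Hz (2 s period) with a 3 mm
    abdominal shift. Optional seeded white displacement jitter supports
    robustness tests and is off by default.
    """
    _check_rate(rate_hz, sample_rate_hz)
    if peak_to_peak_m < 0:
        raise ValueError("peak-to-peak displacement must be non-negative")
    n = _n_samples(duration_s, sample_rate_hz)
    t = np.arange(n) / sample_rate_hz
    x = 0.5 * peak_to_peak_m * np.sin(2.0 * np.pi * rate_hz * t)
    x = x + _jitter(n, jitter_std_m, seed)
    return MotionSignal(x, sample_rate_hz, regime="normal")


def accelerated_breathing(
    rate_hz: float = 1.2,
    peak_to_peak_m: float = 3e-3,
    drift_amplitude_m: float = 1.5e-3,
    drift_rate_hz: float = 0.05,
    duration_s: float = 60.0,
    sample_rate_hz: float = 100.0,
    jitter_std_m: float = 0.0,
    seed: int | None = None,
) -> MotionSignal:
    """Accelerated breathing with a slow body-movement drift.

    A breathing sinusoid at ``rate_hz`` plus an additive drift sinusoid
    at ``drift_rate_hz`` (which must lie below the breathing rate, i.e.
    below the analysis band, so the in-band dominant peak stays at the
    breathing frequency). Defaults: 1.2 Hz breathing, 0.05 Hz drift of
    comparable (half peak-to-peak) amplitude.
    """
    _check_rate(rate_hz, sample_rate_hz)
    if drift_rate_hz < 0:
        raise ValueError("drift rate must be non-negative")
    if drift_amplitude_m < 0:
        raise ValueError("drift amplitude must be non-negative")
    if drift_amplitude_m > 0 and drift_rate_hz >= rate_hz:
        raise ValueError(
            "drift rate must be below the breathing rate "
            f"(got drift {drift_rate_hz} Hz >= rate {rate_hz} Hz)"
        )
    n = _n_samples(duration_s, sample_rate_hz)
    t = np.arange(n) / sample_rate_hz
    x = 0.5 * peak_to_peak_m * np.sin(2.0 * np.pi * rate_hz * t)
    if drift_amplitude_m > 0:
        x = x + drift_amplitude_m * np.sin(2.0 * np.pi * drift_rate_hz * t)
    x = x + _jitter(n, jitter_std_m, seed)
    return MotionSignal(x, sample_rate_hz, regime="accelerated")


def interrupted_breathing(
    segments: Sequence[tuple[str, float]],
    rate_hz: float = 0.5,
    peak_to_peak_m: float = 3e-3,
    sample_rate_hz: float = 100.0,
) -> MotionSignal:
    """Breathing interrupted by apnea episodes.

    ``segments`` is an ordered schedule of ``("breathing", duration_s)``
    and ``("apnea", duration_s)`` entries. The trace is continuous at
    every join: the sinusoid's phase is frozen during apnea (the chest
    holds its last position rather than snapping to zero) and resumes
    where it left off. An all-breathing schedule therefore reproduces
    :func:`normal_breathing` of the same total duration exactly.
    """
    segments = list(segments)
    if not segments:
        raise EmptyScheduleError("breathing schedule has no segments")
    _check_rate(rate_hz, sample_rate_hz)
    increments = []
    for kind, duration_s in segments:
        if kind not in ("breathing", "apnea"):
            raise ValueError(f"unknown segment kind {kind!r}")
        if not duration_s > 0:
            raise ValueError("segment durations must be positive")
        n = _n_samples(duration_s, sample_rate_hz)
        step = 1.0 / sample_rate_hz if kind == "breathing" else 0.0
        increments.append(np.full(n, step))
    inc = np.concatenate(increments)
    # breathing-time clock: advances while breathing, frozen in apnea;
    # sample k sees the clock accumulated over samples 0..k-1
    breathing_time = np.concatenate([[0.0], np.cumsum(inc)[:-1]])
    x = 0.5 * peak_to_peak_m * np.sin(2.0 * np.pi * rate_hz * breathing_time)
    return MotionSignal(x, sample_rate_hz, regime="interrupted")


def random_breathing_like(
    seed: int,
    duration_s: float = 20.0,
    sample_rate_hz: float = 100.0,
    peak_to_peak_m: float = 3e-3,
    n_components: int = 4,
    band_hz: tuple[float, float] = (0.2, 1.5),
) -> MotionSignal:
    """Seeded random smooth motion: a sum of sinusoids in a breathing band.

    Draws ``n_components`` sinusoids with frequencies uniform in
    ``band_hz``, random phases and relative amplitudes, then rescales so
    the realised max-minus-min equals ``peak_to_peak_m``. Used for
    round-trip (simulate → demodulate) identity checks over arbitrary
    band-limited motion.
    """
    rng = np.random.default_rng(seed)
    n = _n_samples(duration_s, sample_rate_hz)
    t = np.arange(n) / sample_rate_hz
    freqs = rng.uniform(band_hz[0], band_hz[1], n_components)
    phases = rng.uniform(0.0, 2.0 * np.pi, n_components)
    amps = rng.uniform(0.2, 1.0, n_components)
    x = np.zeros(n)
    for f, ph, a in zip(freqs, phases, amps):
        x += a * np.sin(2.0 * np.pi * f * t + ph)
    span = x.max() - x.min()
    if span > 0:
        x *= peak_to_peak_m / span
    return MotionSignal(x - x.mean(), sample_rate_hz, regime="custom")
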