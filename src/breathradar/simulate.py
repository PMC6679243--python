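"""Baseband I/Q simulation of the CW Doppler return.

The quadrature receiver mixes the return with the transmit reference
and low-pass filters, leaving a complex baseband pair whose phase is
the round-trip propagation phase:

    I(t) = (A/2) * cos(phi(t) + dtheta(t)) + dc_i + n_i(t)
    Q(t) = (A/2) * sin(phi(t) + dtheta(t)) + dc_q + n_q(t)
    phi(t) = -4*pi*f_rf*d0/c - 4*pi*f_rf*x(t)/c,   f_rf = fc - fIF

The simulator produces this closed form directly rather than sampling a
GHz carrier; :func:`simulate_baseband_mixing` provides the explicit
mix-and-filter chain at a scaled-down RF as an internal cross-check of
the closed form. ``dtheta`` is residual transmit phase noise, common to
both branches (the two oscillators share a PLL reference) and zero by
default.

A single-channel receiver keeps only the I branch; its sensitivity to
small motion collapses at the null distances ``d0 = lambda*(1/4+k/4)``,
which :func:`simulate_single_channel` exists to demonstrate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import signal as sps

from .exceptions import AliasingError, ConfigMismatchError, NearWavelengthWarning
from .motion import MotionSignal
from .radar import PropagationChannel, RadarConfig, wavelength


@dataclass(frozen=True)
class TxWaveform:
    """Unit-amplitude transmit I/Q pair at the intermediate frequency."""

    in_phase: np.ndarray
    quadrature: np.ndarray
    sample_rate_hz: float


@dataclass(frozen=True)
class NoiseModel:
    """Receiver impairments applied to the simulated baseband.

    Parameters
    ----------
    phase_noise_std_rad : float
        Per-sample std of residual transmit phase noise, applied
        identically to I and Q (correlated branches). Default 0: a
        shared PLL reference makes this term common-mode.
    snr_db : float or None
        Additive white Gaussian noise level, as SNR in dB relative to
        the ``A/2`` envelope, equal power per branch. ``None`` disables.
    dc_offset_i, dc_offset_q : float
        Static offsets added to each branch (hardware imbalance).
    seed : int
        Seed for all noise realisations; fixed seed gives bit-identical
        output.
    """

    phase_noise_std_rad: float = 0.0
    snr_db: Optional[float] = None
    dc_offset_i: float = 0.0
    dc_offset_q: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.phase_noise_std_rad < 0:
            raise ValueError("phase-noise std must be non-negative")
        if self.snr_db is not None and not np.isfinite(self.snr_db):
            raise ValueError("snr_db must be finite when enabled")

    @property
    def is_noiseless(self) -> bool:
        return (
            self.phase_noise_std_rad == 0.0
            and self.snr_db is None
            and self.dc_offset_i == 0.0
            and self.dc_offset_q == 0.0
        )


@dataclass(frozen=True)
class BasebandIQ:
    """Low-pass-filtered receiver baseband I/Q pair.

    With all noise disabled the pair lies on a circle of radius ``A/2``
    centred on the origin: ``I**2 + Q**2 == (A/2)**2`` at every sample.
    """

    in_phase: np.ndarray
    quadrature: np.ndarray
    sample_rate_hz: float
    config: Optional[RadarConfig] = None
    channel: Optional[PropagationChannel] = None

    def __post_init__(self) -> None:
        i = np.asarray(self.in_phase, dtype=float)
        q = np.asarray(self.quadrature, dtype=float)
        if i.shape != q.shape or i.ndim != 1:
            raise ValueError("I and Q must be equal-length 1-D series")
        object.__setattr__(self, "in_phase", i)
        object.__setattr__(self, "quadrature", q)

    @property
    def n_samples(self) -> int:
        return self.in_phase.size

    def time_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate_hz

    def envelope(self) -> np.ndarray:
        """Instantaneous magnitude sqrt(I^2 + Q^2)."""
        return np.hypot(self.in_phase, self.quadrature)


def synthesize_tx(
    config: RadarConfig,
    duration_s: float,
    seed: int | None = None,
) -> TxWaveform:
    """Transmit cos/sin pair at the intermediate frequency.

    Samples ``I = cos(2*pi*fIF*t + theta(t))``,
    ``Q = sin(2*pi*fIF*t + theta(t))`` on the config's sample grid,
    with ``theta`` a seeded white phase-noise realisation of std
    ``config.tx_phase_noise_std_rad`` (identically zero by default).
    Requires ``fs > 2*fIF`` to represent the IF tone.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    if config.intermediate_frequency_hz > 0 and (
        config.sample_rate_hz <= 2.0 * config.intermediate_frequency_hz
    ):
        raise AliasingError(
            f"sample rate {config.sample_rate_hz} Hz cannot represent the "
            f"{config.intermediate_frequency_hz} Hz intermediate frequency"
        )
    n = int(round(duration_s * config.sample_rate_hz))
    t = np.arange(n) / config.sample_rate_hz
    theta = np.zeros(n)
    if config.tx_phase_noise_std_rad > 0:
        rng = np.random.default_rng(seed)
        theta = rng.normal(0.0, config.tx_phase_noise_std_rad, n)
    arg = 2.0 * np.pi * config.intermediate_frequency_hz * t + theta
    return TxWaveform(np.cos(arg), np.sin(arg), config.sample_rate_hz)


def baseband_phase(
    motion: MotionSignal,
    channel: PropagationChannel,
    config: RadarConfig,
) -> np.ndarray:
    """Noise-free modulated phase phi(t) = -4*pi*f_rf*(d0 + x(t))/c (rad)."""
    f_rf = config.rf_frequency_hz
    c = config.propagation_speed
    return (
        -4.0 * np.pi * f_rf * channel.nominal_distance_m / c
        - 4.0 * np.pi * f_rf * motion.samples / c
    )


def _validate(motion: MotionSignal, channel: PropagationChannel, config: RadarConfig) -> None:
    if motion.sample_rate_hz != config.sample_rate_hz:
        raise ConfigMismatchError(
            f"motion sampled at {motion.sample_rate_hz} Hz but radar "
            f"config expects {config.sample_rate_hz} Hz"
        )
    lam = wavelength(config)
    if np.max(np.abs(motion.samples), initial=0.0) >= lam:
        warnings.warn(
            "motion amplitude reaches the carrier wavelength; the "
            "small-oscillation assumption is violated",
            NearWavelengthWarning,
            stacklevel=3,
        )
    if channel.nominal_distance_m >= lam:
        warnings.warn(
            f"nominal distance {channel.nominal_distance_m} m is >= the "
            f"wavelength {lam:.4g} m; absolute range is only recoverable "
            "modulo lambda/2 (oscillation recovery is unaffected)",
            NearWavelengthWarning,
            stacklevel=3,
        )


def _modulated_phase(
    motion: MotionSignal,
    channel: PropagationChannel,
    config: RadarConfig,
    noise: NoiseModel,
    rng: np.random.Generator,
) -> np.ndarray:
    phi = baseband_phase(motion, channel, config)
    if noise.phase_noise_std_rad > 0:
        phi = phi + rng.normal(0.0, noise.phase_noise_std_rad, phi.size)
    return phi


def simulate_baseband(
    motion: MotionSignal,
    channel: PropagationChannel,
    config: RadarConfig,
    noise: NoiseModel | None = None,
) -> BasebandIQ:
    """Simulate the quadrature receiver's low-pass-filtered baseband.

    Returns the closed-form post-mixer pair with envelope ``A/2``,
    optional common-mode phase noise, per-branch additive noise, and
    static DC offsets. With ``noise=None`` the output is deterministic
    and exactly on-circle.
    """
    noise = noise or NoiseModel()
    _validate(motion, channel, config)
    rng = np.random.default_rng(noise.seed)
    phi = _modulated_phase(motion, channel, config, noise, rng)
    half_a = 0.5 * channel.attenuation
    i = half_a * np.cos(phi)
    q = half_a * np.sin(phi)
    if noise.snr_db is not None:
        sigma = half_a * 10.0 ** (-noise.snr_db / 20.0)
        i = i + rng.normal(0.0, sigma, i.size)
        q = q + rng.normal(0.0, sigma, q.size)
    i = i + noise.dc_offset_i
    q = q + noise.dc_offset_q
    return BasebandIQ(i, q, config.sample_rate_hz, config=config, channel=channel)


def simulate_single_channel(
    motion: MotionSignal,
    channel: PropagationChannel,
    config: RadarConfig,
    noise: NoiseModel | None = None,
) -> np.ndarray:
    """Single-channel (I-only) receiver output.

    Kept solely to exhibit the null-detection-point failure: at
    ``d0 = lambda*(1/4 + k/4)`` the cosine is at an extremum and small
    motion enters only at second order, suppressing the fundamental
    spectral line that the quadrature chain recovers at any distance.
    """
    noise = noise or NoiseModel()
    _validate(motion, channel, config)
    rng = np.random.default_rng(noise.seed)
    phi = _modulated_phase(motion, channel, config, noise, rng)
    half_a = 0.5 * channel.attenuation
    i = half_a * np.cos(phi)
    if noise.snr_db is not None:
        sigma = half_a * 10.0 ** (-noise.snr_db / 20.0)
        i = i + rng.normal(0.0, sigma, i.size)
    return i + noise.dc_offset_i


def simulate_baseband_mixing(
    motion: MotionSignal,
    channel: PropagationChannel,
    config: RadarConfig,
    oversample: int = 200,
) -> BasebandIQ:
    """Explicit homodyne chain: delay, mix against quadrature LOs, LPF.

    Validation path for the closed form of :func:`simulate_baseband`.
    The return ``A*cos(2*pi*f_rf*(t - tau(t)))`` is sampled on a grid
    oversampled ``oversample``-fold relative to the baseband rate
    (which must exceed the Nyquist rate of ``f_rf`` — use a scaled-down
    RF), mixed with ``cos`` / ``-sin`` local oscillators, low-pass
    filtered to kill the ``2*f_rf`` images, and decimated back to the
    baseband grid. Only practical for demonstration-scale configs.
    """
    f_rf = config.rf_frequency_hz
    fs_rf = config.sample_rate_hz * oversample
    if fs_rf <= 2.0 * f_rf:
        raise AliasingError(
            f"oversampled rate {fs_rf} Hz cannot represent the RF carrier "
            f"{f_rf} Hz; use a scaled-down config for the explicit chain"
        )
    _validate(motion, channel, config)
    n_bb = motion.n_samples
    t = np.arange(n_bb * oversample) / fs_rf
    # zero-order-hold the motion onto the RF grid
    x = np.repeat(motion.samples, oversample)
    tau = 2.0 * (channel.nominal_distance_m + x) / config.propagation_speed
    rx = channel.attenuation * np.cos(2.0 * np.pi * f_rf * (t - tau))
    lo_arg = 2.0 * np.pi * f_rf * t
    mixed_i = rx * np.cos(lo_arg)
    mixed_q = rx * -np.sin(lo_arg)
    # LPF passes the motion band, rejects the 2*f_rf image and guards
    # the subsequent decimation
    cutoff = 0.4 * config.sample_rate_hz
    sos = sps.butter(8, cutoff, btype="low", fs=fs_rf, output="sos")
    i_bb = sps.sosfiltfilt(sos, mixed_i)[::oversample]
    q_bb = sps.sosfiltfilt(sos, mixed_q)[::oversample]
    return BasebandIQ(
        i_bb, q_bb, config.sample_rate_hz, config=config, channel=channel
    )
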