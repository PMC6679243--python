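"""Radar configuration and the closed-form geometry of the CW Doppler link.

A continuous-wave radar observes a breathing chest as a phase-modulated
return: the round-trip propagation delay ``tau(t) = 2(d0 + x(t))/c``
maps chest displacement ``x(t)`` onto the phase of the received carrier.
This module holds the physical constants and configuration shared by the
whole chain, plus the classic detection-point geometry: a single-channel
receiver is maximally sensitive at the *optimum* distances
``d0 = lambda*(1/8 + k/4)`` and blind (to first order) at the *null*
distances ``d0 = lambda*(1/4 + k/4)``; a quadrature receiver is
insensitive to ``d0`` altogether.

Units are SI throughout (metres, seconds, hertz); the reporting layer
converts to millimetres and breaths per minute.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import GeometryError, RadarConfigError

#: Speed of light in vacuum (m/s), the default propagation speed.
C_VACUUM = 299_792_458.0


@dataclass(frozen=True)
class RadarConfig:
    """Static configuration of the software-defined radar link.

    The transceiver synthesises its CW tone at an intermediate frequency
    ``fIF`` and up-converts to the carrier, so the effective RF on the
    air is ``fc - fIF``; every physical quantity (wavelength, phase
    sensitivity) depends only on that difference. Defaults give an
    effective RF of 2.0 GHz (``fc`` = 2.02 GHz, ``fIF`` = 20 MHz), near
    the top of a typical low-cost SDR transceiver's range, where
    displacement sensitivity is highest.

    Parameters
    ----------
    carrier_frequency_hz : float
        Carrier frequency ``fc`` in Hz.
    intermediate_frequency_hz : float
        Intermediate frequency ``fIF`` in Hz; must satisfy
        ``0 <= fIF < fc``.
    propagation_speed : float
        Wave speed ``c`` in m/s (vacuum light speed by default).
    sample_rate_hz : float
        Baseband sampling rate in Hz.
    tx_phase_noise_std_rad : float
        Standard deviation of the transmit oscillator phase noise per
        sample, in radians. Defaults to zero: with a shared PLL
        reference the residual transmit phase noise is common to both
        receiver branches and cancels from the demodulated phase.
    """

    carrier_frequency_hz: float = 2.02e9
    intermediate_frequency_hz: float = 2.0e7
    propagation_speed: float = C_VACUUM
    sample_rate_hz: float = 100.0
    tx_phase_noise_std_rad: float = 0.0

    def __post_init__(self) -> None:
        if not self.intermediate_frequency_hz >= 0:
            raise RadarConfigError(
                f"intermediate frequency must be >= 0, got "
                f"{self.intermediate_frequency_hz!r}"
            )
        if not self.carrier_frequency_hz > self.intermediate_frequency_hz:
            raise RadarConfigError(
                f"carrier frequency ({self.carrier_frequency_hz!r} Hz) must "
                f"exceed the intermediate frequency "
                f"({self.intermediate_frequency_hz!r} Hz)"
            )
        if not self.propagation_speed > 0:
            raise RadarConfigError("propagation speed must be positive")
        if not self.sample_rate_hz > 0:
            raise RadarConfigError("sample rate must be positive")
        if self.tx_phase_noise_std_rad < 0:
            raise RadarConfigError("phase-noise std must be non-negative")

    @property
    def rf_frequency_hz(self) -> float:
        """Effective radiated frequency ``fc - fIF`` (Hz)."""
        return self.carrier_frequency_hz - self.intermediate_frequency_hz

    @property
    def wavelength_m(self) -> float:
        """Wavelength of the effective RF carrier (m)."""
        return wavelength(self)


@dataclass(frozen=True)
class PropagationChannel:
    """One-target free-space channel: nominal distance and a scalar gain.

    ``attenuation`` is the overall amplitude factor ``A`` collecting the
    radar cross-section and propagation losses; the received baseband
    envelope is ``A/2``. No path-loss formula is applied — ``A`` is a
    single dimensionless scalar.
    """

    nominal_distance_m: float
    attenuation: float = 1.0

    def __post_init__(self) -> None:
        if not self.nominal_distance_m >= 0:
            raise GeometryError(
                f"nominal distance must be >= 0, got {self.nominal_distance_m!r}"
            )
        if not self.attenuation > 0:
            raise GeometryError(
                f"attenuation must be > 0, got {self.attenuation!r}"
            )


def wavelength(config: RadarConfig) -> float:
    """Wavelength ``c / (fc - fIF)`` of the effective RF carrier, in metres."""
    return config.propagation_speed / config.rf_frequency_hz


def round_trip_delay(
    channel: PropagationChannel,
    displacement,
    config: RadarConfig,
):
    """Round-trip propagation delay ``2*(d0 + x)/c`` in seconds.

    ``displacement`` may be a scalar or an array; the result has the
    same shape. Raises :class:`GeometryError` if any instantaneous
    target position ``d0 + x`` is negative (target behind the antenna).
    """
    x = np.asarray(displacement, dtype=float)
    position = channel.nominal_distance_m + x
    if np.any(position < 0):
        raise GeometryError(
            "instantaneous target position d0 + x(t) is negative"
        )
    tau = 2.0 * position / config.propagation_speed
    return float(tau) if np.isscalar(displacement) else tau


def optimum_detection_points(config: RadarConfig, k_max: int) -> np.ndarray:
    """Distances ``lambda*(1/8 + k/4)`` for k = 0..k_max, ascending (m).

    At these distances a single-channel receiver's output is linear in
    small chest motion (maximum sensitivity).
    """
    if k_max < 0:
        raise ValueError(f"k_max must be >= 0, got {k_max!r}")
    k = np.arange(k_max + 1)
    return wavelength(config) * (0.125 + 0.25 * k)


def null_detection_points(config: RadarConfig, k_max: int) -> np.ndarray:
    """Distances ``lambda*(1/4 + k/4)`` for k = 0..k_max, ascending (m).

    At these distances a single-channel receiver is insensitive to small
    motion to first order — the failure mode the quadrature receiver
    eliminates.
    """
    if k_max < 0:
        raise ValueError(f"k_max must be >= 0, got {k_max!r}")
    k = np.arange(k_max + 1)
    return wavelength(config) * (0.25 + 0.25 * k)
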