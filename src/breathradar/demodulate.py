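"""Arctangent demodulation: baseband I/Q back to chest displacement.

The modulated phase is recovered with the four-quadrant arctangent
``gamma(t) = atan2(Q, I)``, unwrapped over time (jumps larger than pi
folded back by 2*pi), and inverted to displacement:

    xbar(t) = -gamma(t) * c / (4*pi*(fc - fIF))

A two-quadrant arctan of Q/I would lose track whenever the total phase
(static d0 term plus motion excursion) leaves (-pi/2, pi/2); the
four-quadrant form plus unwrapping tracks the rotating baseband vector
continuously, which is what makes recovery independent of the nominal
distance — including at the single-channel null points. The absolute
distance d0 is only recoverable modulo lambda/2 (one unwrapping
ambiguity of 2*pi in phase), so the default output is the mean-removed
oscillation; the raw unwrapped displacement is available by passing
``remove_mean=False``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateSampleError, IllConditionedArcWarning
from .radar import RadarConfig
from .simulate import BasebandIQ

#: Minimum minor/major extent ratio of the (I, Q) point cloud for the
#: DC-offset circle fit; below this the arc is too flat to fit stably.
_CIRCLE_FIT_FLATNESS_MIN = 1e-2


@dataclass(frozen=True)
class DisplacementSignal:
    """Recovered displacement xbar(t) and its modulated phase gamma(t).

    Invariant: ``displacement_m == -phase_rad * c / (4*pi*f_rf)``
    sample-by-sample; when ``mean_removed`` is set both series are
    zero-mean (the same constant was subtracted from each, in the
    appropriate units).
    """

    displacement_m: np.ndarray
    phase_rad: np.ndarray
    sample_rate_hz: float
    mean_removed: bool = True

    def __post_init__(self) -> None:
        d = np.asarray(self.displacement_m, dtype=float)
        p = np.asarray(self.phase_rad, dtype=float)
        if d.shape != p.shape or d.ndim != 1:
            raise ValueError("displacement and phase must be equal-length 1-D")
        object.__setattr__(self, "displacement_m", d)
        object.__setattr__(self, "phase_rad", p)

    @property
    def n_samples(self) -> int:
        return self.displacement_m.size

    def time_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate_hz


def extract_phase(iq: BasebandIQ, unwrap: bool = True) -> np.ndarray:
    """Quadrant-correct instantaneous phase of the I/Q pair, radians.

    Uses atan2 and (by default) temporal unwrapping with a pi
    threshold, so the returned series is continuous and equals the
    simulator's modulated phase up to one additive multiple of 2*pi.
    Raises :class:`DegenerateSampleError` where I = Q = 0 (zero
    envelope: phase undefined).
    """
    i, q = iq.in_phase, iq.quadrature
    if not (np.all(np.isfinite(i)) and np.all(np.isfinite(q))):
        raise DegenerateSampleError("I/Q contain non-finite samples")
    zero = (i == 0.0) & (q == 0.0)
    if np.any(zero):
        k = int(np.flatnonzero(zero)[0])
        raise DegenerateSampleError(
            f"zero envelope (I = Q = 0) at sample {k}; phase undefined"
        )
    gamma = np.arctan2(q, i)
    if unwrap:
        gamma = np.unwrap(gamma)
    return gamma


def arctangent_demodulate(
    iq: BasebandIQ,
    config: RadarConfig,
    remove_mean: bool = True,
    correct_dc: bool = False,
) -> DisplacementSignal:
    """Invert the unwrapped phase to displacement.

    Parameters
    ----------
    iq : BasebandIQ
        Receiver baseband pair.
    config : RadarConfig
        Supplies ``c`` and the effective RF ``fc - fIF``.
    remove_mean : bool
        Subtract the time mean, discarding the static d0 offset and the
        2*pi*k unwrapping ambiguity and leaving the oscillation x(t)
        alone (default). With ``False`` the raw unwrapped xbar = d0 +
        x(t) is returned, valid modulo lambda/2.
    correct_dc : bool
        Estimate and subtract static I/Q offsets with
        :func:`estimate_dc_offsets` before phase extraction.
    """
    if correct_dc:
        ci, cq = estimate_dc_offsets(iq)
        iq = BasebandIQ(
            iq.in_phase - ci,
            iq.quadrature - cq,
            iq.sample_rate_hz,
            config=iq.config,
            channel=iq.channel,
        )
    gamma = extract_phase(iq)
    scale = config.propagation_speed / (4.0 * np.pi * config.rf_frequency_hz)
    if remove_mean:
        gamma = gamma - gamma.mean()
    xbar = -gamma * scale
    return DisplacementSignal(
        xbar, gamma, iq.sample_rate_hz, mean_removed=remove_mean
    )


def estimate_dc_offsets(iq: BasebandIQ) -> tuple[float, float]:
    """Least-squares centre of the I/Q arc (algebraic circle fit).

    With noise off the baseband samples lie on a circle of radius A/2;
    hardware DC offsets translate that circle off the origin. Fitting
    ``I^2 + Q^2 = a*I + b*Q + c`` by linear least squares (Kasa fit)
    gives the centre ``(a/2, b/2)`` directly — deterministic, no
    iteration. The fit needs the samples to span an appreciable arc:
    below ~a quarter turn the normal matrix is ill-conditioned and the
    function warns and falls back to zero offsets.
    """
    i, q = iq.in_phase, iq.quadrature
    if i.size < 8:
        raise ValueError("need at least 8 samples for the circle fit")
    design = np.column_stack([i, q, np.ones_like(i)])
    rhs = i**2 + q**2
    # arc-coverage check: a short arc is a nearly 1-D point cloud, and
    # the fit's normal matrix degenerates with it.  The minor/major
    # extent ratio of the centred cloud is ~theta/8 for arc angle theta.
    cloud = np.column_stack([i - i.mean(), q - q.mean()])
    sv = np.linalg.svd(cloud, compute_uv=False)
    if sv[0] == 0.0 or sv[1] / sv[0] < _CIRCLE_FIT_FLATNESS_MIN:
        warnings.warn(
            "I/Q arc spans too little phase for a stable circle fit; "
            "assuming zero DC offsets",
            IllConditionedArcWarning,
            stacklevel=2,
        )
        return (0.0, 0.0)
    coef, *_ = np.linalg.lstsq(design, rhs, rcond=None)
    return (0.5 * float(coef[0]), 0.5 * float(coef[1]))
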