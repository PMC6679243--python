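"""In-process pipeline: one call from configuration to report."""

from __future__ import annotations

from dataclasses import dataclass

from .config import PipelineConfig
from .demodulate import DisplacementSignal, arctangent_demodulate
from .motion import MotionSignal
from .respiration import RespirationReport, analyze
from .simulate import BasebandIQ, simulate_baseband


@dataclass(frozen=True)
class PipelineResult:
    motion: MotionSignal
    iq: BasebandIQ
    displacement: DisplacementSignal
    report: RespirationReport


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """simulate → demodulate → analyze, all in memory.

    Deterministic for a fixed configuration (the single seed drives
    every stochastic element).
    """
    motion = config.build_motion()
    iq = simulate_baseband(
        motion, config.channel(), config.radar_config(), config.noise_model()
    )
    displacement = arctangent_demodulate(iq, config.radar_config())
    report = analyze(
        displacement.displacement_m,
        displacement.sample_rate_hz,
        **config.analysis_kwargs(),
    )
    return PipelineResult(motion, iq, displacement, report)
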