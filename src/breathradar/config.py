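"""Pipeline configuration: one human-editable YAML file drives the chain.

The file has five blocks — ``radar``, ``channel``, ``noise``,
``motion`` and ``analysis`` — plus a top-level ``seed``. Every key has
a documented default (see DEFAULTS), so an empty file is a valid,
fully deterministic normal-breathing simulation. Each block is
validated by the owning module's types before any stage runs.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Optional

import yaml

from .motion import (
    MotionSignal,
    accelerated_breathing,
    interrupted_breathing,
    normal_breathing,
)
from .radar import PropagationChannel, RadarConfig, wavelength
from .simulate import NoiseModel

#: Full default configuration. ``channel.nominal_distance_m: null``
#: means "an optimum detection point, lambda/8, for the radar block".
DEFAULTS: dict[str, Any] = {
    "seed": 0,
    "radar": {
        "carrier_frequency_hz": 2.02e9,
        "intermediate_frequency_hz": 2.0e7,
        "sample_rate_hz": 100.0,
        "phase_noise_std_rad": 0.0,
    },
    "channel": {
        "nominal_distance_m": None,
        "attenuation": 1.0,
    },
    "noise": {
        "snr_db": None,
        "phase_noise_std_rad": 0.0,
        "dc_offset_i": 0.0,
        "dc_offset_q": 0.0,
    },
    "motion": {
        "regime": "normal",
        "rate_hz": 0.5,
        "peak_to_peak_m": 3e-3,
        "duration_s": 60.0,
        "drift_amplitude_m": 1.5e-3,
        "drift_rate_hz": 0.05,
        "jitter_std_m": 0.0,
        "schedule": [["breathing", 20.0], ["apnea", 10.0], ["breathing", 20.0]],
    },
    "analysis": {
        "band_hz": [0.1, 3.0],
        "smoothing_span_s": 0.25,
        "trim_fraction": 0.05,
        "apnea_window_s": 4.0,
        "apnea_threshold_m": 1e-3,
    },
}


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        where = f"{path}.{key}" if path else key
        if key not in base:
            raise KeyError(f"unknown configuration key {where!r}")
        if isinstance(base[key], dict):
            if not isinstance(value, dict):
                raise TypeError(f"{where!r} must be a mapping")
            out[key] = _merge(base[key], value, where)
        else:
            out[key] = value
    return out


@dataclass(frozen=True)
class PipelineConfig:
    """Validated configuration for a full simulate→demodulate→analyze run."""

    data: dict[str, Any]

    @classmethod
    def from_dict(cls, overrides: Optional[dict] = None) -> "PipelineConfig":
        cfg = cls(_merge(DEFAULTS, overrides or {}))
        cfg.radar_config()  # validate eagerly
        cfg.channel()
        cfg.noise_model()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        loaded = yaml.safe_load(text) or {}
        if not isinstance(loaded, dict):
            raise TypeError(f"{path}: top level must be a mapping")
        return cls.from_dict(loaded)

    def with_overrides(self, overrides: dict) -> "PipelineConfig":
        return PipelineConfig.from_dict(_merge(self.data, overrides))

    @property
    def seed(self) -> int:
        return int(self.data["seed"])

    def radar_config(self) -> RadarConfig:
        r = self.data["radar"]
        return RadarConfig(
            carrier_frequency_hz=float(r["carrier_frequency_hz"]),
            intermediate_frequency_hz=float(r["intermediate_frequency_hz"]),
            sample_rate_hz=float(r["sample_rate_hz"]),
            tx_phase_noise_std_rad=float(r["phase_noise_std_rad"]),
        )

    def channel(self) -> PropagationChannel:
        c = self.data["channel"]
        d0 = c["nominal_distance_m"]
        if d0 is None:
            d0 = wavelength(self.radar_config()) / 8.0
        return PropagationChannel(
            nominal_distance_m=float(d0),
            attenuation=float(c["attenuation"]),
        )

    def noise_model(self) -> NoiseModel:
        n = self.data["noise"]
        snr = n["snr_db"]
        return NoiseModel(
            phase_noise_std_rad=float(n["phase_noise_std_rad"]),
            snr_db=None if snr is None else float(snr),
            dc_offset_i=float(n["dc_offset_i"]),
            dc_offset_q=float(n["dc_offset_q"]),
            seed=self.seed,
        )

    def build_motion(self) -> MotionSignal:
        m = self.data["motion"]
        fs = float(self.data["radar"]["sample_rate_hz"])
        regime = m["regime"]
        if regime == "normal":
            return normal_breathing(
                rate_hz=float(m["rate_hz"]),
                peak_to_peak_m=float(m["peak_to_peak_m"]),
                duration_s=float(m["duration_s"]),
                sample_rate_hz=fs,
                jitter_std_m=float(m["jitter_std_m"]),
                seed=self.seed,
            )
        if regime == "accelerated":
            return accelerated_breathing(
                rate_hz=float(m["rate_hz"]),
                peak_to_peak_m=float(m["peak_to_peak_m"]),
                drift_amplitude_m=float(m["drift_amplitude_m"]),
                drift_rate_hz=float(m["drift_rate_hz"]),
                duration_s=float(m["duration_s"]),
                sample_rate_hz=fs,
                jitter_std_m=float(m["jitter_std_m"]),
                seed=self.seed,
            )
        if regime == "interrupted":
            schedule = [(str(kind), float(dur)) for kind, dur in m["schedule"]]
            return interrupted_breathing(
                schedule,
                rate_hz=float(m["rate_hz"]),
                peak_to_peak_m=float(m["peak_to_peak_m"]),
                sample_rate_hz=fs,
            )
        raise ValueError(f"unknown motion regime {regime!r}")

    def analysis_kwargs(self) -> dict[str, Any]:
        a = self.data["analysis"]
        from .respiration import default_smoothing_window

        fs = float(self.data["radar"]["sample_rate_hz"])
        return {
            "band_hz": tuple(float(v) for v in a["band_hz"]),
            "smoothing_window": default_smoothing_window(
                fs, float(a["smoothing_span_s"])
            ),
            "trim_fraction": float(a["trim_fraction"]),
            "apnea_window_s": float(a["apnea_window_s"]),
            "apnea_threshold_m": float(a["apnea_threshold_m"]),
        }

    def canonical_json(self) -> str:
        return json.dumps(self.data, sort_keys=True, separators=(",", ":"))

    def digest(self) -> str:
        """SHA-256 of the canonical JSON form, for run manifests."""
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()
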