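"""File formats: CSV time series, raw interleaved I/Q, report JSON.

Dialects
--------
* Motion / displacement: two-column CSV ``time_s,displacement_m`` with a
  one-line header.
* Baseband I/Q, CSV: three columns ``time_s,i,q``.
* Baseband I/Q, raw: little-endian 32-bit floats, interleaved I before
  Q, with a JSON metadata sidecar ``<path>.json`` carrying
  ``sample_rate_hz`` (required), and optionally ``carrier_offset_hz``,
  ``attenuation``, ``seed`` and ``num_samples``.

Floats are written with 17 significant digits, so CSV round-trips are
lossless for float64 and identical inputs give byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import numpy as np

from .demodulate import DisplacementSignal
from .exceptions import (
    EmptyRecordError,
    LengthMismatchError,
    MalformedRowError,
    MissingSidecarError,
)
from .motion import MotionSignal
from .respiration import RespirationReport
from .simulate import BasebandIQ

PathLike = Union[str, Path]

_FMT = "%.17g"


def _read_csv_columns(path: PathLike, header: str, n_cols: int) -> np.ndarray:
    """Parse a headered CSV of floats, reporting bad rows by line number."""
    lines = Path(path).read_text().splitlines()
    if not lines or (len(lines) == 1 and not lines[0].strip()):
        raise EmptyRecordError(f"{path}: file is empty")
    start = 1 if lines[0].strip() == header else 0
    rows = []
    for lineno, line in enumerate(lines[start:], start=start + 1):
        if not line.strip():
            continue
        cells = line.split(",")
        if len(cells) != n_cols:
            raise MalformedRowError(
                f"expected {n_cols} columns, found {len(cells)}", lineno
            )
        try:
            rows.append([float(c) for c in cells])
        except ValueError as exc:
            raise MalformedRowError(str(exc), lineno) from None
    if not rows:
        raise EmptyRecordError(f"{path}: no data rows")
    return np.asarray(rows, dtype=float)


def _infer_fs(time_s: np.ndarray, path: PathLike) -> float:
    if time_s.size < 2:
        raise EmptyRecordError(f"{path}: need >= 2 samples to infer sample rate")
    steps = np.diff(time_s)
    if np.any(steps <= 0) or not np.allclose(steps, steps[0], rtol=1e-6):
        raise MalformedRowError("time column is not uniformly increasing", 2)
    return 1.0 / float(steps[0])


# ---------------------------------------------------------------- motion

MOTION_HEADER = "time_s,displacement_m"


def write_motion_csv(motion: MotionSignal, path: PathLike) -> None:
    data = np.column_stack([motion.time_s(), motion.samples])
    np.savetxt(path, data, fmt=_FMT, delimiter=",", header=MOTION_HEADER,
               comments="")


def read_motion_csv(path: PathLike) -> MotionSignal:
    data = _read_csv_columns(path, MOTION_HEADER, 2)
    fs = _infer_fs(data[:, 0], path)
    return MotionSignal(data[:, 1], fs)


# ----------------------------------------------------------- displacement

DISPLACEMENT_HEADER = "time_s,displacement_m"


def write_displacement_csv(sig: DisplacementSignal, path: PathLike) -> None:
    data = np.column_stack([sig.time_s(), sig.displacement_m])
    np.savetxt(path, data, fmt=_FMT, delimiter=",",
               header=DISPLACEMENT_HEADER, comments="")


def read_displacement_csv(path: PathLike) -> tuple[np.ndarray, float]:
    """Returns (displacement_m, sample_rate_hz)."""
    data = _read_csv_columns(path, DISPLACEMENT_HEADER, 2)
    fs = _infer_fs(data[:, 0], path)
    return data[:, 1], fs


# ------------------------------------------------------------------- I/Q

IQ_HEADER = "time_s,i,q"


def write_iq_csv(iq: BasebandIQ, path: PathLike) -> None:
    data = np.column_stack([iq.time_s(), iq.in_phase, iq.quadrature])
    np.savetxt(path, data, fmt=_FMT, delimiter=",", header=IQ_HEADER,
               comments="")


def read_iq_csv(path: PathLike) -> BasebandIQ:
    data = _read_csv_columns(path, IQ_HEADER, 3)
    fs = _infer_fs(data[:, 0], path)
    return BasebandIQ(data[:, 1], data[:, 2], fs)


def _sidecar_path(path: PathLike) -> Path:
    return Path(str(path) + ".json")


def write_iq_raw(iq: BasebandIQ, path: PathLike, **metadata) -> None:
    """Raw interleaved little-endian float32 I,Q pairs plus JSON sidecar."""
    interleaved = np.empty(2 * iq.n_samples, dtype="<f4")
    interleaved[0::2] = iq.in_phase
    interleaved[1::2] = iq.quadrature
    interleaved.tofile(path)
    sidecar = {"sample_rate_hz": iq.sample_rate_hz,
               "num_samples": iq.n_samples}
    if iq.config is not None:
        sidecar["carrier_offset_hz"] = iq.config.rf_frequency_hz
    if iq.channel is not None:
        sidecar["attenuation"] = iq.channel.attenuation
    sidecar.update(metadata)
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2) + "\n")


def read_iq_raw(path: PathLike) -> BasebandIQ:
    sidecar_file = _sidecar_path(path)
    if not sidecar_file.exists():
        raise MissingSidecarError(
            f"raw I/Q file {path} has no metadata sidecar {sidecar_file}"
        )
    sidecar = json.loads(sidecar_file.read_text())
    if "sample_rate_hz" not in sidecar:
        raise MissingSidecarError(
            f"{sidecar_file}: missing required key 'sample_rate_hz'"
        )
    interleaved = np.fromfile(path, dtype="<f4")
    if interleaved.size == 0:
        raise EmptyRecordError(f"{path}: file is empty")
    if interleaved.size % 2 != 0:
        raise LengthMismatchError(
            f"{path}: odd float count {interleaved.size}; not I,Q interleaved"
        )
    n = interleaved.size // 2
    declared = sidecar.get("num_samples")
    if declared is not None and declared != n:
        raise LengthMismatchError(
            f"{path}: sidecar declares {declared} samples, file has {n}"
        )
    return BasebandIQ(
        interleaved[0::2].astype(float),
        interleaved[1::2].astype(float),
        float(sidecar["sample_rate_hz"]),
    )


def write_iq(iq: BasebandIQ, path: PathLike, dialect: str = "csv") -> None:
    if dialect == "csv":
        write_iq_csv(iq, path)
    elif dialect == "raw":
        write_iq_raw(iq, path)
    else:
        raise ValueError(f"unknown I/Q dialect {dialect!r}")


def read_iq(path: PathLike, dialect: str = "csv") -> BasebandIQ:
    if dialect == "csv":
        return read_iq_csv(path)
    if dialect == "raw":
        return read_iq_raw(path)
    raise ValueError(f"unknown I/Q dialect {dialect!r}")


# ---------------------------------------------------------------- report


def write_report(report: RespirationReport, path: PathLike) -> None:
    Path(path).write_text(report.to_json() + "\n")


def read_report(path: PathLike) -> dict:
    return json.loads(Path(path).read_text())
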