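"""Exception and warning hierarchy for breathradar.

All package errors derive from :class:`BreathRadarError` so callers can
catch the whole family; each concrete class maps to one failure mode of
the signal chain.
"""


class BreathRadarError(ValueError):
    """Base class for all breathradar errors."""


class RadarConfigError(BreathRadarError):
    """Radar configuration violates a physical constraint (e.g. fc <= fIF)."""


class GeometryError(BreathRadarError):
    """Target geometry is unphysical (target behind the antenna)."""


class AliasingError(BreathRadarError):
    """Requested sampling rate cannot resolve the signal to be generated."""


class ConfigMismatchError(BreathRadarError):
    """Two pipeline stages disagree on a shared parameter (sample rate)."""


class DegenerateSampleError(BreathRadarError):
    """I and Q are both zero at some sample; the phase is undefined there."""


class EmptyScheduleError(BreathRadarError):
    """A breathing schedule contains no segments."""


class BadWindowError(BreathRadarError):
    """A filter/analysis window is even, non-positive, or longer than the record."""


class TooShortRecordError(BreathRadarError):
    """The record is too short for the requested spectral analysis."""


class EmptyBandError(BreathRadarError):
    """The requested analysis band contains no spectral bins."""


class FileFormatError(BreathRadarError):
    """Base class for file I/O format errors."""


class MalformedRowError(FileFormatError):
    """A CSV row could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


class MissingSidecarError(FileFormatError):
    """Raw I/Q file has no JSON metadata sidecar."""


class EmptyRecordError(FileFormatError):
    """An input file contains no samples."""


class LengthMismatchError(FileFormatError):
    """I and Q series (or declared and actual lengths) disagree."""


class NearWavelengthWarning(UserWarning):
    """Motion amplitude or nominal distance approaches the wavelength."""


class IllConditionedArcWarning(UserWarning):
    """I/Q arc spans too little phase for a stable DC-offset circle fit."""
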