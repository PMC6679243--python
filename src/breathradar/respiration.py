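"""Respiration analysis of the recovered displacement waveform.

Turns the demodulated chest displacement into the clinically meaningful
quantities: a smoothed waveform, its magnitude spectrum, the dominant
breathing frequency and rate in breaths/min, the peak-to-peak abdominal
shift, and apnea (interrupted-breathing) intervals found by sliding-
window excursion thresholding.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from scipy.signal.windows import hann

from .exceptions import BadWindowError, EmptyBandError, TooShortRecordError

#: Default analysis band (Hz): covers human breathing (both the resting
#: ~0.5 Hz and accelerated ~1.2 Hz regimes) while excluding DC and
#: sub-0.1 Hz body-movement drift.
DEFAULT_BAND_HZ = (0.1, 3.0)

#: Default moving-average span in seconds: well below the breathing
#: period, so noise is smoothed without materially attenuating the
#: breathing component.
DEFAULT_SMOOTHING_S = 0.25

#: Zero-padding factor for spectra.  An integer multiple of the record
#: length keeps every original DFT bin on the padded grid, so an
#: exact-bin motion frequency is reported exactly.
SPECTRUM_PAD_FACTOR = 4


@dataclass(frozen=True)
class Spectrum:
    """One-sided magnitude spectrum on a uniform non-negative grid."""

    frequency_hz: np.ndarray
    magnitude: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.frequency_hz, dtype=float)
        m = np.asarray(self.magnitude, dtype=float)
        if f.shape != m.shape or f.ndim != 1 or f.size < 2:
            raise ValueError("frequency and magnitude must be equal-length 1-D")
        object.__setattr__(self, "frequency_hz", f)
        object.__setattr__(self, "magnitude", m)

    @property
    def resolution_hz(self) -> float:
        """Grid step Δf (Hz)."""
        return float(self.frequency_hz[1] - self.frequency_hz[0])


@dataclass(frozen=True)
class RespirationReport:
    """Summary of one respiration record.

    ``rate_bpm`` is exactly ``60 * dominant_frequency_hz``;
    ``peak_to_peak_m`` is the (default trim-quantile, smoothed)
    abdominal shift and ``peak_to_peak_raw_m`` the plain max-minus-min
    of the unsmoothed displacement. Apnea segments are half-open
    ``[start_s, end_s)`` intervals from record start.
    """

    dominant_frequency_hz: float
    rate_bpm: float
    peak_to_peak_m: float
    peak_to_peak_raw_m: float
    apnea_segments_s: tuple[tuple[float, float], ...]
    analysis_band_hz: tuple[float, float]
    duration_s: float

    def __post_init__(self) -> None:
        if self.rate_bpm != 60.0 * self.dominant_frequency_hz:
            raise ValueError("rate_bpm must equal 60 * dominant_frequency_hz")
        lo, hi = self.analysis_band_hz
        if not lo <= self.dominant_frequency_hz <= hi:
            raise ValueError("dominant frequency outside the analysis band")
        prev_end = 0.0
        for start, end in self.apnea_segments_s:
            if not (prev_end <= start < end <= self.duration_s + 1e-9):
                raise ValueError("apnea segments must be ordered, disjoint, "
                                 "and within the record duration")
            prev_end = end

    def to_dict(self) -> dict:
        return {
            "dominant_frequency_hz": self.dominant_frequency_hz,
            "rate_bpm": self.rate_bpm,
            "peak_to_peak_m": self.peak_to_peak_m,
            "peak_to_peak_raw_m": self.peak_to_peak_raw_m,
            "apnea_segments_s": [list(seg) for seg in self.apnea_segments_s],
            "analysis_band_hz": list(self.analysis_band_hz),
            "duration_s": self.duration_s,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def summary(self) -> str:
        """Human-readable summary (mm and breaths/min)."""
        lines = [
            f"dominant frequency : {self.dominant_frequency_hz:.4g} Hz",
            f"breathing rate     : {self.rate_bpm:.4g} breaths/min",
            f"peak-to-peak shift : {self.peak_to_peak_m * 1e3:.3g} mm "
            f"(raw {self.peak_to_peak_raw_m * 1e3:.3g} mm)",
        ]
        if self.apnea_segments_s:
            segs = ", ".join(
                f"[{s:.1f} s, {e:.1f} s)" for s, e in self.apnea_segments_s
            )
            lines.append(f"apnea episodes     : {segs}")
        else:
            lines.append("apnea episodes     : none")
        return "\n".join(lines)


def moving_average(signal: np.ndarray, window: int) -> np.ndarray:
    """Centred moving mean with shrinking windows at the edges.

    ``window`` must be odd (so the window centres on a sample) and no
    longer than the record; the output has the record's length.
    """
    x = np.asarray(signal, dtype=float)
    if window < 1 or window % 2 == 0:
        raise BadWindowError(f"window must be odd and >= 1, got {window!r}")
    if window > x.size:
        raise BadWindowError(
            f"window ({window}) exceeds record length ({x.size})"
        )
    kernel = np.ones(window)
    sums = np.convolve(x, kernel, mode="same")
    counts = np.convolve(np.ones_like(x), kernel, mode="same")
    return sums / counts


def default_smoothing_window(
    sample_rate_hz: float, span_s: float = DEFAULT_SMOOTHING_S
) -> int:
    """Moving-average window for a time span, rounded to the nearest odd count."""
    n = max(1, int(round(span_s * sample_rate_hz)))
    return n if n % 2 == 1 else n + 1


def spectral_analysis(
    signal: np.ndarray,
    sample_rate_hz: float,
    pad_factor: int = SPECTRUM_PAD_FACTOR,
) -> Spectrum:
    """Magnitude spectrum of the mean-removed, Hann-windowed signal.

    The transform length is ``pad_factor`` times the record length;
    Δf = fs / (pad_factor * N). The magnitude is normalised so a
    unit-amplitude exact-bin sinusoid reads 1.0 at its bin.
    """
    x = np.asarray(signal, dtype=float)
    if x.size < 16:
        raise TooShortRecordError(
            f"need >= 16 samples for spectral analysis, got {x.size}"
        )
    if not np.all(np.isfinite(x)):
        raise ValueError("signal must be finite")
    if pad_factor < 1:
        raise ValueError("pad_factor must be >= 1")
    n = x.size
    w = hann(n, sym=False)
    xw = (x - x.mean()) * w
    nfft = pad_factor * n
    mag = np.abs(np.fft.rfft(xw, n=nfft)) / w.sum() * 2.0
    freqs = np.fft.rfftfreq(nfft, d=1.0 / sample_rate_hz)
    return Spectrum(freqs, mag)


def dominant_frequency(
    spectrum: Spectrum, band_hz: tuple[float, float] = DEFAULT_BAND_HZ
) -> float:
    """Frequency of maximum magnitude inside the band; ties go low.

    The band's lower edge must be positive (DC excluded)."""
    lo, hi = band_hz
    if not 0 < lo < hi:
        raise ValueError(f"need 0 < band low < band high, got {band_hz!r}")
    mask = (spectrum.frequency_hz >= lo) & (spectrum.frequency_hz <= hi)
    if not np.any(mask):
        raise EmptyBandError(f"no spectral bins inside {band_hz!r}")
    f_band = spectrum.frequency_hz[mask]
    m_band = spectrum.magnitude[mask]
    return float(f_band[int(np.argmax(m_band))])


def breaths_per_minute(frequency_hz: float) -> float:
    """Convert a breathing frequency in Hz to breaths per minute (60*f)."""
    if frequency_hz < 0:
        raise ValueError("frequency must be non-negative")
    return 60.0 * frequency_hz


def peak_to_peak_amplitude(
    signal: np.ndarray, trim_fraction: float = 0.0
) -> float:
    """Robust peak-to-peak: upper minus lower trim quantile.

    ``trim_fraction = 0`` gives plain max-minus-min; a small positive
    trim discards extreme excursions so additive noise does not inflate
    the estimate.
    """
    x = np.asarray(signal, dtype=float)
    if x.size == 0:
        raise ValueError("signal must be non-empty")
    if not 0.0 <= trim_fraction < 0.5:
        raise ValueError("trim_fraction must be in [0, 0.5)")
    hi, lo = np.quantile(x, [1.0 - trim_fraction, trim_fraction])
    return float(hi - lo)


def detect_apnea(
    signal: np.ndarray,
    sample_rate_hz: float,
    window_s: float = 4.0,
    threshold_m: float = 1e-3,
) -> list[tuple[float, float]]:
    """Find intervals where breathing excursion falls below threshold.

    A centred sliding window of length ``window_s`` (recommended: at
    least two breathing periods) computes the local peak-to-peak
    displacement at every sample; samples whose window excursion is
    below ``threshold_m`` are apneic, and contiguous runs merge into
    half-open ``[start_s, end_s)`` intervals. Interval edges are
    accurate to within one window length, since windows straddling a
    breathing/apnea boundary see the breathing excursion. The detector
    depends only on within-window excursion, so constant displacement
    offsets do not change the result.
    """
    x = np.asarray(signal, dtype=float)
    if threshold_m <= 0:
        raise ValueError("threshold must be positive")
    w = int(round(window_s * sample_rate_hz))
    if w < 2:
        raise BadWindowError(f"window must span >= 2 samples, got {w}")
    if w > x.size:
        raise BadWindowError(
            f"window ({window_s} s = {w} samples) exceeds the record "
            f"({x.size} samples)"
        )
    local_p2p = (
        ndimage.maximum_filter1d(x, size=w, mode="nearest")
        - ndimage.minimum_filter1d(x, size=w, mode="nearest")
    )
    apneic = local_p2p < threshold_m
    intervals: list[tuple[float, float]] = []
    edges = np.flatnonzero(np.diff(apneic.astype(int)))
    starts = list(edges[~apneic[edges]] + 1)
    ends = list(edges[apneic[edges]] + 1)
    if apneic[0]:
        starts.insert(0, 0)
    if apneic[-1]:
        ends.append(x.size)
    for s, e in zip(starts, ends):
        intervals.append((s / sample_rate_hz, e / sample_rate_hz))
    return intervals


def analyze(
    displacement: np.ndarray,
    sample_rate_hz: float,
    band_hz: tuple[float, float] = DEFAULT_BAND_HZ,
    smoothing_window: Optional[int] = None,
    trim_fraction: float = 0.05,
    apnea_window_s: float = 4.0,
    apnea_threshold_m: float = 1e-3,
) -> RespirationReport:
    """Full post-processing: smooth, spectrum, rate, shift, apnea.

    ``smoothing_window`` defaults to 0.25 s worth of samples (odd).
    The reported ``peak_to_peak_m`` is the trim-quantile excursion of
    the smoothed waveform; ``peak_to_peak_raw_m`` is max-minus-min of
    the input as given.
    """
    x = np.asarray(displacement, dtype=float)
    if smoothing_window is None:
        smoothing_window = default_smoothing_window(sample_rate_hz)
    smoothed = moving_average(x, smoothing_window)
    spectrum = spectral_analysis(smoothed, sample_rate_hz)
    f0 = dominant_frequency(spectrum, band_hz)
    segments = detect_apnea(
        smoothed, sample_rate_hz, window_s=apnea_window_s,
        threshold_m=apnea_threshold_m,
    )
    return RespirationReport(
        dominant_frequency_hz=f0,
        rate_bpm=breaths_per_minute(f0),
        peak_to_peak_m=peak_to_peak_amplitude(smoothed, trim_fraction),
        peak_to_peak_raw_m=peak_to_peak_amplitude(x, 0.0),
        apnea_segments_s=tuple(segments),
        analysis_band_hz=tuple(band_hz),
        duration_s=x.size / sample_rate_hz,
    )
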