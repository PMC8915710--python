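"""Beat detection and waveform feature extraction.

Features mirror the constructions used for Valsalva-based volume
assessment: per-beat pulse amplitude, half-height width, and
area-under-the-curve; per-window means/SDs plus the RMS power of the
mean-subtracted signal; and per-trial end-Valsalva / end-rest ratios,
whose attenuation reflects preload reduction during strain.

The detector is deliberately plain: zero-phase low-pass smoothing, a
rolling-median detrend, and prominence-gated peak picking with a
physiologic refractory period.  All thresholds are relative to the signal
scale, so features are equivariant under amplitude scaling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter
from scipy.signal import butter, filtfilt, find_peaks

from .errors import DetectionError, WidthError, WindowingError
from .synthetic_cohort import ManeuverAnnotation, WaveformRecording

__all__ = [
    "Beat",
    "WindowFeatures",
    "TrialFeatures",
    "detect_beats",
    "beat_metrics",
    "window_features",
    "trial_features",
]

log = logging.getLogger(__name__)

_MIN_DURATION_S = 3.0
_REFRACTORY_S = 0.33  # >= 0.33 s between peaks, i.e. <= ~180 bpm
_PROMINENCE_FRACTION = 0.25  # of the 5-95% detrended signal span
_LOWPASS_HZ = 8.0


@dataclass(frozen=True)
class Beat:
    """One detected beat: foot -> systolic peak -> next foot."""

    foot_index: int
    peak_index: int
    next_foot_index: int
    amplitude: float  # AU, peak above foot level
    width: float  # s, at half amplitude above foot
    auc: float  # AU*s, area above foot level over the beat

    def __post_init__(self) -> None:
        if not self.foot_index < self.peak_index < self.next_foot_index:
            raise WidthError("beat indices must satisfy foot < peak < next_foot")
        if self.amplitude <= 0 or self.width <= 0 or self.auc <= 0:
            raise WidthError("beat metrics must be positive")


@dataclass(frozen=True)
class WindowFeatures:
    window_id: str  # {end_rest, end_valsalva}
    mean_amplitude: float
    sd_amplitude: float
    mean_width: float
    mean_auc: float
    rms_power: float
    n_beats: int


@dataclass(frozen=True)
class TrialFeatures:
    end_rest: WindowFeatures
    end_valsalva: WindowFeatures
    ratio_rms: float
    ratio_auc: float
    ratio_amplitude: float


def _smooth(x: np.ndarray, fs: float) -> np.ndarray:
    """Zero-phase low-pass; pass-through when the band is unusable."""
    nyq = fs / 2.0
    cut = min(_LOWPASS_HZ, 0.8 * nyq)
    if cut <= 0 or cut >= nyq:
        return x
    b, a = butter(3, cut / nyq)
    return filtfilt(b, a, x)


def detect_beats(rec: WaveformRecording) -> list[Beat]:
    """Detect beats and compute their metrics.

    Peaks are local maxima of the smoothed, median-detrended signal whose
    prominence exceeds a fraction of the robust signal span, separated by
    at least the refractory period; feet are the smoothed-signal minima
    between consecutive peaks.  Metrics are evaluated on the raw samples.
    The first and last peaks of the recording lack a flanking foot and are
    not returned as beats; beats whose half-height width is undefined are
    dropped and logged.
    """
    if rec.duration < _MIN_DURATION_S:
        raise DetectionError(
            f"recording of {rec.duration:.2f} s is too short (need >= 3 s)"
        )
    x = rec.samples
    fs = rec.sampling_rate
    smoothed = _smooth(x, fs)
    win = max(3, int(round(fs)) | 1)
    detrended = smoothed - median_filter(smoothed, size=win, mode="nearest")
    lo, hi = np.quantile(detrended, [0.05, 0.95])
    span = hi - lo
    if span <= 0:
        raise DetectionError("signal has no pulsatile component")
    peaks, _ = find_peaks(
        detrended,
        prominence=_PROMINENCE_FRACTION * span,
        distance=max(1, int(round(_REFRACTORY_S * fs))),
    )
    if len(peaks) < 3:
        raise DetectionError(f"detected only {max(len(peaks) - 1, 0)} beats (need >= 2)")
    feet = np.array(
        [p0 + int(np.argmin(smoothed[p0:p1])) for p0, p1 in zip(peaks[:-1], peaks[1:])]
    )
    beats: list[Beat] = []
    for k in range(1, len(peaks) - 1):
        foot, peak, nxt = int(feet[k - 1]), int(peaks[k]), int(feet[k])
        try:
            amplitude, width, auc = beat_metrics(rec, foot, peak, nxt)
            beats.append(
                Beat(
                    foot_index=foot,
                    peak_index=peak,
                    next_foot_index=nxt,
                    amplitude=amplitude,
                    width=width,
                    auc=auc,
                )
            )
        except WidthError as exc:
            log.info("dropping beat at sample %d: %s", peak, exc)
    if len(beats) < 2:
        raise DetectionError("fewer than 2 usable beats after metric screening")
    return beats


def beat_metrics(
    rec: WaveformRecording, foot_index: int, peak_index: int, next_foot_index: int
) -> tuple[float, float, float]:
    """Amplitude, half-height width, and AUC of one beat on the raw trace.

    amplitude = x[peak] - x[foot]; width = time between the up- and
    down-crossings of (foot level + amplitude/2) around the peak, with
    linear interpolation between samples; auc = trapezoidal integral of
    (x - foot level) from foot to next foot.
    """
    if not 0 <= foot_index < peak_index < next_foot_index < len(rec.samples):
        raise WidthError("beat indices out of range or out of order")
    x = rec.samples
    fs = rec.sampling_rate
    base = x[foot_index]
    amplitude = x[peak_index] - base
    if amplitude <= 0:
        raise WidthError("non-positive amplitude")
    half = base + amplitude / 2.0

    rising = x[foot_index : peak_index + 1]
    below = np.nonzero(rising < half)[0]
    if len(below) == 0:
        raise WidthError("half-height level never crossed on the upstroke")
    i = below[-1]  # last sample below the half level before the peak
    if i == len(rising) - 1:
        raise WidthError("upstroke crossing at the peak itself")
    t_up = foot_index + i + (half - rising[i]) / (rising[i + 1] - rising[i])

    falling = x[peak_index : next_foot_index + 1]
    under = np.nonzero(falling < half)[0]
    if len(under) == 0:
        raise WidthError("half-height level never re-crossed on the downstroke")
    j = under[0]
    if j == 0:
        raise WidthError("downstroke crossing at the peak itself")
    t_dn = peak_index + j - 1 + (falling[j - 1] - half) / (falling[j - 1] - falling[j])

    width = (t_dn - t_up) / fs
    if width <= 0:
        raise WidthError("non-positive width")
    seg = x[foot_index : next_foot_index + 1] - base
    auc = float(np.trapezoid(seg, dx=1.0 / fs))
    if auc <= 0:
        raise WidthError("non-positive area under the beat")
    return float(amplitude), float(width), auc


def window_features(
    rec: WaveformRecording,
    beats: list[Beat],
    window: tuple[float, float],
    window_id: str,
) -> WindowFeatures:
    """Aggregate beat metrics over a half-open time window (s from t0).

    Beats belong to the window if their peak time falls in [start, end).
    SD uses the n-1 denominator; rms_power is the RMS of the
    mean-subtracted raw samples inside the window.
    """
    start, end = window
    fs = rec.sampling_rate
    peak_t = np.array([b.peak_index / fs for b in beats])
    mask = (peak_t >= start) & (peak_t < end)
    selected = [b for b, m in zip(beats, mask) if m]
    if len(selected) < 2:
        raise WindowingError(
            f"window {window_id} [{start:g}, {end:g}) s holds "
            f"{len(selected)} beats (need >= 2)"
        )
    amps = np.array([b.amplitude for b in selected])
    i0 = int(np.ceil(start * fs - 1e-9))
    i1 = int(np.ceil(end * fs - 1e-9))
    seg = rec.samples[max(i0, 0) : min(i1, len(rec.samples))]
    rms = float(np.sqrt(np.mean((seg - seg.mean()) ** 2)))
    return WindowFeatures(
        window_id=window_id,
        mean_amplitude=float(amps.mean()),
        sd_amplitude=float(amps.std(ddof=1)),
        mean_width=float(np.mean([b.width for b in selected])),
        mean_auc=float(np.mean([b.auc for b in selected])),
        rms_power=rms,
        n_beats=len(selected),
    )


def trial_features(
    rec: WaveformRecording, ann: ManeuverAnnotation, window_len: float = 5.0
) -> TrialFeatures:
    """End-rest and end-Valsalva aggregates plus their attenuation ratios.

    The analysis windows are the terminal ``window_len`` seconds of the
    rest and strain phases; ratios are end-Valsalva / end-rest, so normal
    attenuation gives values below 1 and a blunted (volume-overloaded)
    response gives values near 1.
    """
    if window_len <= 0:
        raise WindowingError("window_len must be positive")
    rest_len = ann.rest_window[1] - ann.rest_window[0]
    strain_len = ann.strain_window[1] - ann.strain_window[0]
    if window_len > rest_len or window_len > strain_len:
        raise WindowingError(
            f"window_len {window_len:g} s exceeds a maneuver phase "
            f"(rest {rest_len:g} s, strain {strain_len:g} s)"
        )
    if ann.recovery_window[1] > rec.duration + 1.0 / rec.sampling_rate:
        raise WindowingError("annotation extends beyond the recording")
    beats = detect_beats(rec)
    end_rest = window_features(
        rec, beats, (ann.rest_window[1] - window_len, ann.rest_window[1]), "end_rest"
    )
    end_vals = window_features(
        rec,
        beats,
        (ann.strain_window[1] - window_len, ann.strain_window[1]),
        "end_valsalva",
    )
    return TrialFeatures(
        end_rest=end_rest,
        end_valsalva=end_vals,
        ratio_rms=end_vals.rms_power / end_rest.rms_power,
        ratio_auc=end_vals.mean_auc / end_rest.mean_auc,
        ratio_amplitude=end_vals.mean_amplitude / end_rest.mean_amplitude,
    )
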