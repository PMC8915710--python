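"""Synthetic cohorts of finger-PPG Valsalva recordings.

The generator emulates the clinical protocol used for noninvasive volume
assessment in cirrhosis: each subject performs three Valsalva maneuvers
(10 s of strain at a 25 mmHg mouth-pressure target, separated by 1 min of
rest) while a fingertip photoplethysmogram is recorded.  Intravascular
filling pressure (LVEDP/PCWP) is the latent trait: subjects are drawn from
a two-component truncated-normal mixture (volume-overloaded vs not), and
the pulse-amplitude response to strain encodes that pressure — at low
filling pressure the pulse amplitude collapses during strain (normal
physiology), while at high pressure the response is blunted and the
amplitude barely changes.

The attenuation map, pulse morphology, and noise model are modeling
choices (the clinical literature reports only amplitude behavior, not a
parametric dose-response); see docs/methods.md for the rationale behind
each default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.special import expit
from scipy.stats import truncnorm

from .errors import ConfigError, UsageError

__all__ = [
    "TrialLayout",
    "SimConfig",
    "WaveformRecording",
    "ManeuverAnnotation",
    "SubjectRecord",
    "draw_filling_pressure",
    "valsalva_attenuation",
    "synthesize_trial",
    "simulate_bnp",
    "simulate_cohort",
    "pulse_template",
    "PULSE_PEAK_PHASE",
]

# Asymmetric single-peak pulse template p(u) = u^2 (1-u)^5, u in [0, 1),
# normalized to unit peak: fast systolic upstroke, slower diastolic decay.
PULSE_PEAK_PHASE = 2.0 / 7.0
_TEMPLATE_PEAK = PULSE_PEAK_PHASE**2 * (1.0 - PULSE_PEAK_PHASE) ** 5


def pulse_template(u: np.ndarray) -> np.ndarray:
    """Evaluate the unit-amplitude pulse shape at phase ``u`` in [0, 1)."""
    u = np.asarray(u, dtype=float)
    out = np.zeros_like(u)
    inside = (u >= 0.0) & (u < 1.0)
    ui = u[inside]
    out[inside] = ui**2 * (1.0 - ui) ** 5 / _TEMPLATE_PEAK
    return out


@dataclass(frozen=True)
class TrialLayout:
    """Timing of one Valsalva trial, seconds."""

    rest_s: float = 30.0
    strain_s: float = 10.0
    recovery_s: float = 15.0
    inter_trial_rest_s: float = 60.0

    @property
    def duration_s(self) -> float:
        return self.rest_s + self.strain_s + self.recovery_s


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the synthetic cohort.

    Pressure mixture defaults reproduce the published group summaries for
    cirrhotic patients undergoing catheterization: ~35% overload prevalence
    with filling pressures of 23.67 (6.00) mmHg in the overloaded group vs
    10.59 (3.02) mmHg otherwise, split at the 15 mmHg clinical cutoff.
    """

    # --- latent pressure mixture (mmHg) ---
    prevalence_overload: float = 0.35
    pressure_mean_overload: float = 23.67
    pressure_sd_overload: float = 6.00
    pressure_mean_normal: float = 10.59
    pressure_sd_normal: float = 3.02
    overload_threshold: float = 15.0
    # --- demographics ---
    age_mean: float = 62.6
    age_sd: float = 10.4
    # --- cardiovascular signal ---
    heart_rate_mean: float = 72.0  # beats/min
    heart_rate_sd: float = 9.0
    baseline_amplitude: float = 1.0  # AU, resting pulse height
    r_min: float = 0.4  # attenuation floor (end-strain/rest amplitude)
    attenuation_midpoint: float = 15.0  # mmHg, logistic midpoint P0
    attenuation_scale: float = 3.0  # mmHg, logistic width s
    # --- BNP model: log BNP = a + b * pressure + noise ---
    bnp_intercept: float = 3.4  # log pg/ml at zero pressure
    bnp_slope: float = 0.126  # log pg/ml per mmHg
    bnp_noise_sd: float = 1.6  # log pg/ml
    bnp_assay_max: float = 5000.0  # pg/ml, upper reportable limit
    # --- measurement noise ---
    noise_sd: float = 0.02  # AU, additive white noise
    drift_amplitude: float = 0.10  # AU, slow sinusoidal baseline wander
    drift_freq_hz: float = 0.08
    amp_jitter_sd: float = 0.03  # relative beat-to-beat amplitude variation
    interval_jitter_sd: float = 0.03  # relative beat-interval variation
    subject_amplitude_sd: float = 0.2  # log-scale between-subject gain spread
    # --- strain envelope time course (s) ---
    strain_onset_s: float = 4.0
    recovery_ramp_s: float = 5.0
    # --- acquisition ---
    sampling_rate: float = 100.0  # Hz
    trial_layout: TrialLayout = field(default_factory=TrialLayout)
    n_trials: int = 3
    seed: int = 0

    def validate(self) -> None:
        # Degenerate single-group mixtures (0 or 1) are permitted: they
        # give exact expectations for distribution-level tests.
        if not 0.0 <= self.prevalence_overload <= 1.0:
            raise ConfigError("prevalence_overload must lie in [0, 1]")
        if not 0.0 < self.r_min <= 1.0:
            raise ConfigError("r_min must lie in (0, 1]")
        if self.sampling_rate < 25.0:
            raise ConfigError("sampling_rate must be >= 25 Hz")
        if self.trial_layout.strain_s <= 0:
            raise ConfigError("strain_s must be positive")
        for name in (
            "pressure_sd_overload",
            "pressure_sd_normal",
            "heart_rate_sd",
            "bnp_noise_sd",
            "noise_sd",
            "age_sd",
            "amp_jitter_sd",
            "interval_jitter_sd",
            "subject_amplitude_sd",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if self.attenuation_scale <= 0:
            raise ConfigError("attenuation_scale must be positive")
        if self.n_trials < 1:
            raise ConfigError("n_trials must be >= 1")

    def noiseless(self) -> "SimConfig":
        """Copy with every stochastic nuisance term switched off.

        Keeps the latent physiology (pressure, attenuation, heart rate)
        but removes additive noise, drift, and amplitude/interval jitter,
        so per-beat amplitudes follow the analytic envelope exactly.
        """
        return replace(
            self,
            noise_sd=0.0,
            drift_amplitude=0.0,
            amp_jitter_sd=0.0,
            interval_jitter_sd=0.0,
            subject_amplitude_sd=0.0,
        )


@dataclass(frozen=True)
class WaveformRecording:
    """Uniformly sampled PPG trace."""

    samples: np.ndarray  # AU
    sampling_rate: float  # Hz
    t0: float = 0.0  # s, absolute time of the first sample

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1:
            raise UsageError("samples must be one-dimensional")
        if not np.all(np.isfinite(samples)):
            raise UsageError("samples must be finite")
        if self.sampling_rate <= 0:
            raise UsageError("sampling_rate must be positive")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sampling_rate

    def times(self) -> np.ndarray:
        """Absolute sample times in seconds."""
        return self.t0 + np.arange(len(self.samples)) / self.sampling_rate


@dataclass(frozen=True)
class ManeuverAnnotation:
    """Half-open rest/strain/recovery windows, seconds from ``t0``."""

    rest_window: tuple[float, float]
    strain_window: tuple[float, float]
    recovery_window: tuple[float, float]
    target_mouth_pressure: float = 25.0  # mmHg

    def __post_init__(self) -> None:
        windows = (self.rest_window, self.strain_window, self.recovery_window)
        for lo, hi in windows:
            if not lo < hi:
                raise UsageError("annotation windows must be non-empty")
        if not (
            self.rest_window[1] <= self.strain_window[0]
            and self.strain_window[1] <= self.recovery_window[0]
        ):
            raise UsageError("windows must be ordered rest < strain < recovery")


@dataclass
class SubjectRecord:
    """One simulated (or loaded) patient."""

    subject_id: str
    age: float  # years
    filling_pressure: float  # mmHg
    bnp: float  # pg/ml
    overload_15: bool
    overload_10: bool
    trials: list[tuple[WaveformRecording, ManeuverAnnotation]] = field(
        default_factory=list
    )


def draw_filling_pressure(config: SimConfig, rng: np.random.Generator) -> float:
    """Draw one filling pressure (mmHg) from the two-group mixture.

    With probability ``prevalence_overload`` the draw is
    Normal(mean_overload, sd_overload) truncated to values above the
    overload threshold; otherwise Normal(mean_normal, sd_normal) truncated
    to (0, threshold].  Truncation shifts the realized group means away
    from the nominal parameters (upward for the overloaded group, downward
    for the normal group); the mixture mean lands near the published
    overall summary.
    """
    config.validate()
    if rng.random() < config.prevalence_overload:
        mu, sd = config.pressure_mean_overload, config.pressure_sd_overload
        lo, hi = config.overload_threshold, math.inf
    else:
        mu, sd = config.pressure_mean_normal, config.pressure_sd_normal
        lo, hi = 0.0, config.overload_threshold
    if sd == 0.0:
        if not (lo < mu <= hi):
            raise ConfigError(
                "degenerate pressure component lies outside its truncation region"
            )
        return float(mu)
    a, b = (lo - mu) / sd, (hi - mu) / sd
    return float(truncnorm.rvs(a, b, loc=mu, scale=sd, random_state=rng))


def valsalva_attenuation(pressure: float, config: SimConfig) -> float:
    """End-strain/rest pulse-amplitude ratio as a function of pressure.

    Logistic in pressure: r = r_min + (1 - r_min) * expit((P - P0) / s).
    Low pressure -> ratio near r_min (strong normal attenuation); high
    pressure -> ratio approaching 1 (blunted response of volume overload).
    Strictly increasing in pressure.
    """
    if pressure <= 0:
        raise UsageError("pressure must be positive")
    z = (pressure - config.attenuation_midpoint) / config.attenuation_scale
    return float(config.r_min + (1.0 - config.r_min) * expit(z))


def _strain_envelope(
    t: np.ndarray, layout: TrialLayout, r_end: float, config: SimConfig
) -> np.ndarray:
    """Amplitude modulation m(t): 1 at rest, down to r_end during strain,
    back to 1 in recovery.

    The decline is linear over ``strain_onset_s`` then holds at ``r_end``
    for the remainder of the strain (pulse amplitude settles within a few
    beats of strain onset, so the end-strain window sits on the plateau);
    recovery ramps linearly back to 1 over ``recovery_ramp_s``.
    """
    s0 = layout.rest_s
    s1 = s0 + layout.strain_s
    onset = min(config.strain_onset_s, layout.strain_s)
    ramp = min(config.recovery_ramp_s, layout.recovery_s) or 1.0
    m = np.ones_like(t)
    in_onset = (t >= s0) & (t < s0 + onset)
    m[in_onset] = 1.0 + (r_end - 1.0) * (t[in_onset] - s0) / onset
    plateau = (t >= s0 + onset) & (t < s1)
    m[plateau] = r_end
    in_ramp = (t >= s1) & (t < s1 + ramp)
    m[in_ramp] = r_end + (1.0 - r_end) * (t[in_ramp] - s1) / ramp
    return m


def synthesize_trial(
    pressure: float,
    config: SimConfig,
    rng: np.random.Generator,
    heart_rate: Optional[float] = None,
    amplitude_scale: float = 1.0,
    return_truth: bool = False,
):
    """Render one annotated Valsalva trial for a subject at ``pressure``.

    Returns ``(WaveformRecording, ManeuverAnnotation)``, or a third
    ground-truth dict (beat start/peak times, per-beat amplitudes, the
    attenuation ratio) when ``return_truth`` is set — used by detector
    validation, never by the analysis path.
    """
    config.validate()
    if pressure <= 0:
        raise UsageError("pressure must be positive")
    if heart_rate is None:
        heart_rate = _draw_heart_rate(config, rng)
    beat_hz = heart_rate / 60.0
    if config.sampling_rate < 2.5 * beat_hz:
        raise ConfigError(
            f"sampling_rate {config.sampling_rate} Hz cannot resolve "
            f"{heart_rate:.0f} bpm beats (need >= {2.5 * beat_hz:.1f} Hz)"
        )

    layout = config.trial_layout
    duration = layout.duration_s
    fs = config.sampling_rate
    n_samples = int(round(duration * fs))

    # Beat schedule: mean interval 60/HR with relative jitter.
    mean_ti = 60.0 / heart_rate
    n_beats_max = int(duration / mean_ti * 1.5) + 8
    jitter = np.clip(
        rng.normal(0.0, config.interval_jitter_sd, size=n_beats_max), -0.3, 0.3
    )
    intervals = mean_ti * (1.0 + jitter)
    starts = np.concatenate([[0.0], np.cumsum(intervals)])[:-1]
    keep = starts < duration
    starts, intervals = starts[keep], intervals[keep]

    r_end = valsalva_attenuation(pressure, config)
    envelope = _strain_envelope(starts, layout, r_end, config)
    amp_jitter = rng.normal(0.0, config.amp_jitter_sd, size=len(starts))
    amps = (
        config.baseline_amplitude
        * amplitude_scale
        * envelope
        * np.clip(1.0 + amp_jitter, 0.1, None)
    )

    t = np.arange(n_samples) / fs
    beat_idx = np.searchsorted(starts, t, side="right") - 1
    u = (t - starts[beat_idx]) / intervals[beat_idx]
    signal = amps[beat_idx] * pulse_template(u)

    if config.drift_amplitude > 0:
        phase = rng.uniform(0.0, 2.0 * np.pi)
        signal = signal + config.drift_amplitude * np.sin(
            2.0 * np.pi * config.drift_freq_hz * t + phase
        )
    if config.noise_sd > 0:
        signal = signal + rng.normal(0.0, config.noise_sd, size=n_samples)

    rec = WaveformRecording(samples=signal, sampling_rate=fs, t0=0.0)
    ann = ManeuverAnnotation(
        rest_window=(0.0, layout.rest_s),
        strain_window=(layout.rest_s, layout.rest_s + layout.strain_s),
        recovery_window=(
            layout.rest_s + layout.strain_s,
            duration,
        ),
    )
    if return_truth:
        truth = {
            "beat_starts": starts,
            "peak_times": starts + PULSE_PEAK_PHASE * intervals,
            "amplitudes": amps,
            "envelope": envelope,
            "r_end": r_end,
            "heart_rate": heart_rate,
        }
        return rec, ann, truth
    return rec, ann


def _draw_heart_rate(config: SimConfig, rng: np.random.Generator) -> float:
    if config.heart_rate_sd == 0:
        return config.heart_rate_mean
    a = (40.0 - config.heart_rate_mean) / config.heart_rate_sd
    b = (140.0 - config.heart_rate_mean) / config.heart_rate_sd
    return float(
        truncnorm.rvs(
            a, b, loc=config.heart_rate_mean, scale=config.heart_rate_sd,
            random_state=rng,
        )
    )


def simulate_bnp(pressure: float, config: SimConfig, rng: np.random.Generator) -> float:
    """Draw a BNP value (pg/ml), lognormal around a linear trend in pressure.

    The default noise makes BNP only weakly predictive of pressure, as it
    is clinically: a BNP-only regression attains a cross-validated R^2 of
    roughly 0.2 at moderate cohort sizes.  Values are censored at the
    assay's upper reportable limit, which also bounds the leverage the
    lognormal tail would otherwise exert on a linear fit.
    """
    if pressure <= 0:
        raise UsageError("pressure must be positive")
    log_bnp = (
        config.bnp_intercept
        + config.bnp_slope * pressure
        + (rng.normal(0.0, config.bnp_noise_sd) if config.bnp_noise_sd > 0 else 0.0)
    )
    return float(min(np.exp(log_bnp), config.bnp_assay_max))


def _draw_age(config: SimConfig, rng: np.random.Generator) -> float:
    if config.age_sd == 0:
        return config.age_mean
    a = (18.0 - config.age_mean) / config.age_sd
    b = (95.0 - config.age_mean) / config.age_sd
    return float(
        truncnorm.rvs(a, b, loc=config.age_mean, scale=config.age_sd, random_state=rng)
    )


def simulate_cohort(
    n: int, config: SimConfig, waveforms: bool = True
) -> list[SubjectRecord]:
    """Simulate ``n`` subjects; deterministic for fixed ``(n, config)``.

    Each subject gets an independent substream spawned from the config
    seed, so cohorts are reproducible and subject i's data do not depend
    on n.  With ``waveforms=False`` only covariates and labels are drawn
    (cheap path for distribution-calibration checks at large n).
    """
    config.validate()
    if n < 1:
        raise UsageError("n must be >= 1")
    streams = np.random.SeedSequence(config.seed).spawn(n)
    subjects: list[SubjectRecord] = []
    for i in range(n):
        rng = np.random.default_rng(streams[i])
        age = _draw_age(config, rng)
        pressure = draw_filling_pressure(config, rng)
        bnp = simulate_bnp(pressure, config, rng)
        heart_rate = _draw_heart_rate(config, rng)
        amp_scale = (
            float(np.exp(rng.normal(0.0, config.subject_amplitude_sd)))
            if config.subject_amplitude_sd > 0
            else 1.0
        )
        trials = []
        if waveforms:
            for _ in range(config.n_trials):
                rec, ann = synthesize_trial(
                    pressure, config, rng,
                    heart_rate=heart_rate, amplitude_scale=amp_scale,
                )
                trials.append((rec, ann))
        subjects.append(
            SubjectRecord(
                subject_id=f"S{i:04d}",
                age=age,
                filling_pressure=pressure,
                bnp=bnp,
                overload_15=pressure > 15.0,
                overload_10=pressure > 10.0,
                trials=trials,
            )
        )
    return subjects
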