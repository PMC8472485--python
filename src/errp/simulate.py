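"""Synthetic sham-feedback EEG sessions.

Emulates a sham-BCI experiment: on each trial the participant is cued to
attempt one of four movements and, after a fixed delay, receives "correct" or
"error" feedback scheduled at a fixed ratio, independent of brain activity.
The feedback-locked response carries a fronto-central ERP with a negative peak
near 350 ms and a positive peak near 450 ms; the negative peak is slightly
deeper when the feedback was erroneous (the error-related potential).

Everything is a pure function of (arguments, seed); sessions generated twice
with the same seed are identical.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .montage import default_montage, spatial_weights

__all__ = [
    "FEEDBACK_CORRECT",
    "FEEDBACK_ERROR",
    "CUE",
    "MOVEMENTS",
    "Trial",
    "TrialSchedule",
    "ErpTemplateParams",
    "VariabilityProfile",
    "Recording",
    "make_session_schedule",
    "synthesize_erp_template",
    "synthesize_recording",
    "make_cohort",
]

FEEDBACK_CORRECT = "feedback-correct"
FEEDBACK_ERROR = "feedback-error"
CUE = "cue"
MOVEMENTS = ("left-hand", "right-hand", "left-foot", "right-foot")


@dataclass(frozen=True)
class Trial:
    movement: str
    feedback: str  # "correct" | "error"
    start_s: float


@dataclass(frozen=True)
class TrialSchedule:
    """Ordered trial list plus the fixed phase durations of one trial.

    Timeline per trial: idle (relax) -> preparation text -> movement cue,
    attempted movement -> feedback after ``feedback_delay_s`` -> short tail
    before the next trial starts.
    """

    trials: tuple[Trial, ...]
    idle_s: float = 5.0
    preparation_s: float = 3.0
    feedback_delay_s: float = 3.0
    tail_s: float = 1.5

    def __post_init__(self) -> None:
        starts = [t.start_s for t in self.trials]
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError("trial start times must be strictly increasing")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def n_correct(self) -> int:
        return sum(t.feedback == "correct" for t in self.trials)

    @property
    def n_error(self) -> int:
        return self.n_trials - self.n_correct

    @property
    def trial_duration_s(self) -> float:
        return self.idle_s + self.preparation_s + self.feedback_delay_s + self.tail_s

    def cue_times(self) -> np.ndarray:
        return np.array([t.start_s + self.idle_s + self.preparation_s for t in self.trials])

    def feedback_times(self) -> np.ndarray:
        return self.cue_times() + self.feedback_delay_s

    @property
    def duration_s(self) -> float:
        return self.trials[-1].start_s + self.trial_duration_s if self.trials else 0.0


@dataclass(frozen=True)
class ErpTemplateParams:
    """Two-bump parametric feedback-locked ERP.

    A negative Gaussian bump followed by a positive one; each bump is
    truncated to zero outside +/- 3 widths of its latency.  The ErrP class
    gets ``class_delta_uV`` added to the negative-peak amplitude (negative
    delta = deeper negativity for error feedback).
    """

    neg_peak_latency_ms: float = 350.0
    pos_peak_latency_ms: float = 450.0
    neg_amp_uV: float = -4.0
    pos_amp_uV: float = 3.0
    neg_width_ms: float = 30.0
    pos_width_ms: float = 33.0
    class_delta_uV: float = -2.5
    duration_ms: float = 700.0

    def __post_init__(self) -> None:
        if self.neg_width_ms <= 0 or self.pos_width_ms <= 0:
            raise ValueError("peak widths must be positive")
        for lat in (self.neg_peak_latency_ms, self.pos_peak_latency_ms):
            if not 0 <= lat < self.duration_ms:
                raise ValueError("peak latencies must lie within the template window")


@dataclass(frozen=True)
class VariabilityProfile:
    """Nuisance structure of a simulated cohort.

    ``participant_amp_scale`` and ``day_amp_scale`` are log-normal sigmas of
    multiplicative ERP amplitude factors (drawn once per participant resp.
    per day); ``latency_jitter_ms`` is the per-trial Gaussian latency sigma
    and ``day_latency_shift_ms`` the sigma of a day-constant latency offset.
    ``artifact_epoch_rate`` is the per-trial probability of a high-amplitude
    transient inside the feedback epoch; ``bad_channel_rate`` the per-channel
    probability of a grossly inflated channel for the whole recording.
    """

    participant_amp_scale: float = 0.5
    day_amp_scale: float = 0.25
    latency_jitter_ms: float = 10.0
    day_latency_shift_ms: float = 30.0
    noise_rms_uV: float = 6.0
    alpha_rms_uV: float = 1.0
    artifact_epoch_rate: float = 0.18
    artifact_amp_uV: float = 300.0
    bad_channel_rate: float = 0.008

    def __post_init__(self) -> None:
        for name in ("participant_amp_scale", "day_amp_scale", "latency_jitter_ms",
                     "day_latency_shift_ms", "noise_rms_uV", "alpha_rms_uV",
                     "artifact_amp_uV"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("artifact_epoch_rate", "bad_channel_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class Recording:
    """Continuous multi-channel EEG in microvolts with event markers."""

    channel_labels: list[str]
    fs_hz: float
    signal: np.ndarray  # channels x samples, microvolts
    events: list[tuple[int, str]]  # (sample_index, code)
    participant_id: str = "P01"
    day_id: str = "day1"

    def __post_init__(self) -> None:
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if self.signal.shape[0] != len(self.channel_labels):
            raise ValueError("signal row count must match channel labels")
        n = self.signal.shape[1]
        if any(not 0 <= s < n for s, _ in self.events):
            raise ValueError("event sample indices must lie within the signal")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    def feedback_events(self) -> list[tuple[int, str]]:
        return [(s, c) for s, c in self.events if c in (FEEDBACK_CORRECT, FEEDBACK_ERROR)]


def make_session_schedule(
    n_per_movement: int,
    ratio_correct: float = 0.70,
    seed: int = 0,
    *,
    idle_s: float = 5.0,
    preparation_s: float = 3.0,
    feedback_delay_s: float = 3.0,
    tail_s: float = 1.5,
) -> TrialSchedule:
    """Randomized session of 4*n_per_movement trials with exact feedback counts.

    The number of correct-feedback trials is round(total * ratio_correct);
    the error count absorbs the remainder so the total is preserved.  Movement
    order and the positions of error feedback are permuted by ``seed``.
    """
    if n_per_movement < 1:
        raise ValueError("n_per_movement must be >= 1")
    if not 0.0 < ratio_correct < 1.0:
        raise ValueError("ratio_correct must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    total = 4 * n_per_movement
    n_correct = int(round(total * ratio_correct))
    n_correct = min(max(n_correct, 1), total - 1)  # keep both classes present

    movements = np.repeat(np.arange(4), n_per_movement)
    rng.shuffle(movements)
    feedback = np.array(["correct"] * n_correct + ["error"] * (total - n_correct))
    rng.shuffle(feedback)

    trial_len = idle_s + preparation_s + feedback_delay_s + tail_s
    trials = tuple(
        Trial(MOVEMENTS[m], fb, i * trial_len)
        for i, (m, fb) in enumerate(zip(movements, feedback))
    )
    return TrialSchedule(trials, idle_s, preparation_s, feedback_delay_s, tail_s)


def synthesize_erp_template(
    params: ErpTemplateParams, klass: str, fs_hz: float
) -> np.ndarray:
    """Feedback-locked ERP waveform (microvolts), sample 0 = feedback onset.

    Sum of a negative and a positive Gaussian bump at the configured
    latencies, each truncated to zero outside three widths, so the waveform
    extrema sit exactly at the configured latencies.
    """
    if klass not in ("ErrP", "NonErrP"):
        raise ValueError("class must be 'ErrP' or 'NonErrP'")
    if fs_hz <= 0:
        raise ValueError("fs_hz must be positive")
    n = int(round(params.duration_ms / 1000.0 * fs_hz))
    t_ms = np.arange(n) / fs_hz * 1000.0
    neg_amp = params.neg_amp_uV + (params.class_delta_uV if klass == "ErrP" else 0.0)

    wave = np.zeros(n)
    for amp, lat, width in (
        (neg_amp, params.neg_peak_latency_ms, params.neg_width_ms),
        (params.pos_amp_uV, params.pos_peak_latency_ms, params.pos_width_ms),
    ):
        bump = amp * np.exp(-((t_ms - lat) ** 2) / (2.0 * width**2))
        bump[np.abs(t_ms - lat) > 3.0 * width] = 0.0
        wave += bump
    return wave


def _pink_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
                fs_hz: float, rms_uV: float, alpha_rms_uV: float = 0.0) -> np.ndarray:
    """1/f-shaped Gaussian background, optional 10 Hz rhythm, target RMS in uV."""
    if rms_uV == 0.0 and alpha_rms_uV == 0.0:
        return np.zeros((n_channels, n_samples))
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs_hz)
    # flat below 1 Hz to keep variance finite, 1/f above
    shape = 1.0 / np.sqrt(np.maximum(freqs, 1.0))
    shape[0] = 0.0  # no DC
    out = np.empty((n_channels, n_samples))
    for c in range(n_channels):
        spec = shape * (rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs)))
        x = np.fft.irfft(spec, n=n_samples)
        sd = x.std()
        x = x / sd * rms_uV if sd > 0 else x
        if alpha_rms_uV > 0:
            phase = rng.uniform(0, 2 * np.pi)
            t = np.arange(n_samples) / fs_hz
            x = x + np.sqrt(2.0) * alpha_rms_uV * np.sin(2 * np.pi * 10.0 * t + phase)
        out[c] = x
    return out


def synthesize_recording(
    schedule: TrialSchedule,
    templates: ErpTemplateParams,
    profile: VariabilityProfile,
    montage: list[str] | None = None,
    fs_hz: float = 1200.0,
    seed: int = 0,
    *,
    amp_scale: float = 1.0,
    latency_shift_ms: float = 0.0,
    participant_id: str = "P01",
    day_id: str = "day1",
) -> Recording:
    """Render one session: ERP templates on 1/f background noise.

    One feedback event is emitted per trial with a code matching the scheduled
    feedback type.  The class template — latencies shifted by
    ``latency_shift_ms`` plus per-trial Gaussian jitter, amplitudes scaled by
    ``amp_scale`` — is added feedback-locked, weighted across channels by a
    Gaussian scalp map centred on FCz.  A fraction of trials receive a
    high-amplitude low-frequency transient inside the epoch window (artifact
    epochs); each channel may independently turn "bad" (noise inflated 25x
    for the whole recording).
    """
    if schedule.n_trials == 0:
        raise ValueError("schedule must contain at least one trial")
    if montage is None:
        montage = default_montage()
    if not montage:
        raise ValueError("montage must be non-empty")

    rng = np.random.default_rng(seed)
    n_samples = int(np.ceil(schedule.duration_s * fs_hz)) + 1
    n_ch = len(montage)

    signal = _pink_noise(rng, n_ch, n_samples, fs_hz, profile.noise_rms_uV,
                         profile.alpha_rms_uV)
    bad = rng.random(n_ch) < profile.bad_channel_rate
    signal[bad] *= 25.0

    weights = spatial_weights(montage)
    events: list[tuple[int, str]] = []
    cue_times = schedule.cue_times()
    fb_times = schedule.feedback_times()
    for i, trial in enumerate(schedule.trials):
        cue_sample = int(round(cue_times[i] * fs_hz))
        fb_sample = int(round(fb_times[i] * fs_hz))
        events.append((cue_sample, CUE))
        code = FEEDBACK_CORRECT if trial.feedback == "correct" else FEEDBACK_ERROR
        events.append((fb_sample, code))

        jitter = latency_shift_ms + rng.normal(0.0, profile.latency_jitter_ms) \
            if profile.latency_jitter_ms > 0 else latency_shift_ms
        hi_ms = templates.duration_ms - 1e-9
        params_i = replace(
            templates,
            neg_peak_latency_ms=float(np.clip(templates.neg_peak_latency_ms + jitter, 0.0, hi_ms)),
            pos_peak_latency_ms=float(np.clip(templates.pos_peak_latency_ms + jitter, 0.0, hi_ms)),
        )
        klass = "ErrP" if trial.feedback == "error" else "NonErrP"
        wave = amp_scale * synthesize_erp_template(params_i, klass, fs_hz)
        stop = min(fb_sample + len(wave), n_samples)
        signal[:, fb_sample:stop] += weights[:, None] * wave[: stop - fb_sample]

        if profile.artifact_epoch_rate > 0 and rng.random() < profile.artifact_epoch_rate:
            # slow transient centred inside the 100-500 ms analysis window so
            # it survives the 0.05-10 Hz band-pass and trips the 150 uV rule
            center_s = fb_times[i] + 0.3
            t = np.arange(n_samples) / fs_hz
            lo = int(round((center_s - 0.25) * fs_hz))
            hi = min(int(round((center_s + 0.25) * fs_hz)), n_samples)
            amp = profile.artifact_amp_uV * rng.choice((-1.0, 1.0))
            bump = amp * np.exp(-((t[lo:hi] - center_s) ** 2) / (2 * 0.06**2))
            signal[:, lo:hi] += bump[None, :]

    return Recording(list(montage), fs_hz, signal, events, participant_id, day_id)


def make_cohort(
    n_participants: int,
    n_days: int,
    profile: VariabilityProfile | None = None,
    templates: ErpTemplateParams | None = None,
    seed: int = 0,
    *,
    n_per_movement: int = 100,
    ratio_correct: float = 0.70,
    montage: list[str] | None = None,
    fs_hz: float = 1200.0,
    schedule_kwargs: dict | None = None,
) -> list[Recording]:
    """Simulate a cohort: participant parameters drawn once, day shifts per day.

    Each participant gets one multiplicative ERP amplitude factor (log-normal,
    sigma ``participant_amp_scale``) shared across days; each (participant,
    day) additionally gets a day amplitude factor and a day-constant latency
    shift.  Returns n_participants * n_days recordings with distinct ids.
    """
    if n_participants < 1 or n_days < 1:
        raise ValueError("need at least one participant and one day")
    profile = profile or VariabilityProfile()
    templates = templates or ErpTemplateParams()
    schedule_kwargs = schedule_kwargs or {}

    root = np.random.SeedSequence(seed)
    param_rng = np.random.default_rng(root.spawn(1)[0])
    rec_seeds = root.spawn(n_participants * n_days)

    recordings: list[Recording] = []
    k = 0
    for p in range(n_participants):
        amp_p = float(np.exp(param_rng.normal(0.0, profile.participant_amp_scale))) \
            if profile.participant_amp_scale > 0 else 1.0
        # movement/feedback order is randomized per participant and shared
        # across that participant's days
        schedule = make_session_schedule(
            n_per_movement, ratio_correct,
            seed=int(param_rng.integers(2**31)), **schedule_kwargs
        )
        for d in range(n_days):
            amp_pd = amp_p * (float(np.exp(param_rng.normal(0.0, profile.day_amp_scale)))
                              if profile.day_amp_scale > 0 else 1.0)
            shift_pd = float(param_rng.normal(0.0, profile.day_latency_shift_ms)) \
                if profile.day_latency_shift_ms > 0 else 0.0
            rec = synthesize_recording(
                schedule, templates, profile, montage, fs_hz,
                seed=np.random.default_rng(rec_seeds[k]).integers(2**31),
                amp_scale=amp_pd, latency_shift_ms=shift_pd,
                participant_id=f"P{p + 1:02d}", day_id=f"day{d + 1}",
            )
            recordings.append(rec)
            k += 1
    return recordings
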