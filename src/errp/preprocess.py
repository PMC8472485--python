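"""Feedback-locked epoch preprocessing.

The chain, in order: zero-phase Butterworth band-pass (0.05-10 Hz, order-8
design applied forward-backward), exclusion of channels whose mean absolute
amplitude exceeds the channel population mean by more than 3 SD, extraction
of 400 ms epochs [100, 500) ms after feedback onset, rejection of epochs with
any absolute value exceeding 150 uV, per-channel within-epoch mean
subtraction, and random subsampling of the majority (NonErrP) class down to
the ErrP count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .simulate import FEEDBACK_ERROR, Recording

__all__ = [
    "NONERRP",
    "ERRP",
    "LABEL_NAMES",
    "EpochSet",
    "PreprocessConfig",
    "PreprocessLog",
    "bandpass_filter",
    "detect_bad_channels",
    "extract_epochs",
    "reject_artifact_epochs",
    "normalize_epochs",
    "balance_classes",
    "preprocess_session",
]

logger = logging.getLogger(__name__)

NONERRP = 0
ERRP = 1
LABEL_NAMES = {NONERRP: "NonErrP", ERRP: "ErrP"}


@dataclass
class EpochSet:
    """Trials x channels x samples tensor with per-trial class labels.

    ``window_ms`` is half-open [start, end) relative to feedback onset;
    ``trial_indices`` map each row back to the original feedback-event index
    in the source recording.
    """

    data: np.ndarray  # trials x channels x samples, microvolts
    labels: np.ndarray  # per trial, NONERRP or ERRP
    window_ms: tuple[float, float]
    fs_hz: float
    channel_labels: list[str]
    participant_id: str = "P01"
    day_id: str = "day1"
    trial_indices: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x samples")
        if self.data.shape[0] != len(self.labels):
            raise ValueError("label count must match trial count")
        if self.data.shape[1] != len(self.channel_labels):
            raise ValueError("channel axis must match channel labels")
        expected = int(round((self.window_ms[1] - self.window_ms[0]) / 1000.0 * self.fs_hz))
        if self.data.shape[2] != expected:
            raise ValueError(
                f"window {self.window_ms} at {self.fs_hz} Hz implies {expected} samples, "
                f"got {self.data.shape[2]}"
            )
        if self.trial_indices is None:
            self.trial_indices = np.arange(self.data.shape[0])
        self.trial_indices = np.asarray(self.trial_indices, dtype=int)

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def class_counts(self) -> dict[str, int]:
        return {name: int(np.sum(self.labels == code)) for code, name in LABEL_NAMES.items()}

    def subset(self, index: np.ndarray) -> "EpochSet":
        index = np.asarray(index)
        return EpochSet(
            self.data[index], self.labels[index], self.window_ms, self.fs_hz,
            list(self.channel_labels), self.participant_id, self.day_id,
            self.trial_indices[index],
        )

    def select_channels(self, labels: list[str]) -> "EpochSet":
        """Restrict to the given channels, in the given order."""
        idx = [self.channel_labels.index(lab) for lab in labels]
        return EpochSet(
            self.data[:, idx, :], self.labels, self.window_ms, self.fs_hz,
            list(labels), self.participant_id, self.day_id, self.trial_indices,
        )


@dataclass(frozen=True)
class PreprocessConfig:
    band_hz: tuple[float, float] = (0.05, 10.0)
    filter_order: int = 8
    bad_channel_sd_k: float = 3.0
    epoch_window_ms: tuple[float, float] = (100.0, 500.0)
    reject_amp_uV: float = 150.0
    balance: bool = True

    def __post_init__(self) -> None:
        lo, hi = self.band_hz
        if not 0 < lo < hi:
            raise ValueError("band must satisfy 0 < low < high")
        if self.filter_order < 2 or self.filter_order % 2:
            raise ValueError("filter_order must be even and >= 2")
        if self.bad_channel_sd_k <= 0:
            raise ValueError("bad_channel_sd_k must be positive")
        if self.reject_amp_uV <= 0:
            raise ValueError("reject_amp_uV must be positive")


@dataclass
class PreprocessLog:
    """Per-session exclusion bookkeeping."""

    participant_id: str
    day_id: str
    bad_channels: list[str]
    n_trials: int
    n_rejected: int
    n_errp: int
    n_nonerrp: int
    n_after_balance: int


def design_bandpass(band_hz: tuple[float, float], order: int, fs_hz: float) -> np.ndarray:
    """Second-order sections of the Butterworth band-pass (single pass)."""
    lo, hi = band_hz
    if hi >= fs_hz / 2:
        raise ValueError("band upper edge must be below the Nyquist frequency")
    return sps.butter(order, [lo, hi], btype="bandpass", output="sos", fs=fs_hz)


def bandpass_filter(
    recording: Recording, band_hz: tuple[float, float] = (0.05, 10.0), order: int = 8
) -> Recording:
    """Zero-phase band-pass: the order-``order`` filter run forward-backward.

    Doubles the magnitude roll-off and cancels the phase; events are
    unchanged.
    """
    sos = design_bandpass(band_hz, order, recording.fs_hz)
    padlen = 3 * (2 * sos.shape[0] + 1)
    if recording.n_samples <= padlen:
        raise ValueError(
            f"signal too short for zero-phase filtering (need > {padlen} samples)"
        )
    filtered = sps.sosfiltfilt(sos, recording.signal, axis=1)
    return Recording(
        list(recording.channel_labels), recording.fs_hz, filtered,
        list(recording.events), recording.participant_id, recording.day_id,
    )


def detect_bad_channels(recording: Recording, k: float = 3.0) -> list[str]:
    """Channels whose mean absolute amplitude exceeds mean + k*SD across channels.

    The statistic is the time-averaged |signal| per channel over the whole
    recording (a signed mean of band-passed EEG is ~0 and uninformative).
    """
    if len(recording.channel_labels) < 3:
        raise ValueError("bad-channel detection needs at least 3 channels")
    stats = np.mean(np.abs(recording.signal), axis=1)
    bound = stats.mean() + k * stats.std()
    flagged = [lab for lab, s in zip(recording.channel_labels, stats) if s > bound]
    if flagged:
        logger.info("%s/%s: excluding bad channels %s",
                    recording.participant_id, recording.day_id, flagged)
    return flagged


def extract_epochs(
    recording: Recording,
    window_ms: tuple[float, float] = (100.0, 500.0),
    exclude_channels: list[str] | None = None,
) -> EpochSet:
    """One epoch per feedback event, labelled ErrP for error feedback.

    The window is half-open [start, end) ms relative to the feedback sample.
    Events whose window would run past the recording are dropped with a
    warning rather than raising.
    """
    exclude = set(exclude_channels or ())
    keep_idx = [i for i, lab in enumerate(recording.channel_labels) if lab not in exclude]
    labels_kept = [recording.channel_labels[i] for i in keep_idx]

    fs = recording.fs_hz
    start_off = int(round(window_ms[0] / 1000.0 * fs))
    n_samp = int(round((window_ms[1] - window_ms[0]) / 1000.0 * fs))

    rows, labels, trial_idx = [], [], []
    n_dropped = 0
    for i, (sample, code) in enumerate(recording.feedback_events()):
        a = sample + start_off
        b = a + n_samp
        if a < 0 or b > recording.n_samples:
            n_dropped += 1
            continue
        rows.append(recording.signal[keep_idx, a:b])
        labels.append(ERRP if code == FEEDBACK_ERROR else NONERRP)
        trial_idx.append(i)
    if n_dropped:
        logger.warning("%s/%s: dropped %d feedback events without a full epoch window",
                       recording.participant_id, recording.day_id, n_dropped)
    data = np.stack(rows) if rows else np.empty((0, len(keep_idx), n_samp))
    return EpochSet(
        data, np.array(labels, dtype=int), tuple(window_ms), fs, labels_kept,
        recording.participant_id, recording.day_id, np.array(trial_idx, dtype=int),
    )


def reject_artifact_epochs(epochs: EpochSet, threshold_uV: float = 150.0) -> EpochSet:
    """Drop epochs whose max |value| strictly exceeds the threshold."""
    if epochs.n_epochs == 0:
        return epochs
    peaks = np.max(np.abs(epochs.data), axis=(1, 2))
    keep = peaks <= threshold_uV
    n_rej = int(np.sum(~keep))
    if n_rej:
        logger.info("%s/%s: rejected %d/%d epochs exceeding %g uV",
                    epochs.participant_id, epochs.day_id, n_rej, epochs.n_epochs,
                    threshold_uV)
    return epochs.subset(np.flatnonzero(keep))


def normalize_epochs(epochs: EpochSet) -> EpochSet:
    """Subtract each channel's within-epoch mean (baseline removal)."""
    data = epochs.data - epochs.data.mean(axis=2, keepdims=True)
    return replace_data(epochs, data)


def balance_classes(epochs: EpochSet, seed: int = 0) -> EpochSet:
    """Subsample NonErrP epochs (without replacement) to the ErrP count.

    All ErrP epochs are kept; the retained set is shuffled so class order
    carries no information.
    """
    errp_idx = np.flatnonzero(epochs.labels == ERRP)
    non_idx = np.flatnonzero(epochs.labels == NONERRP)
    if len(errp_idx) == 0 or len(non_idx) == 0:
        raise ValueError("both classes must be present to balance")
    rng = np.random.default_rng(seed)
    n_keep = min(len(errp_idx), len(non_idx))
    non_kept = rng.choice(non_idx, size=n_keep, replace=False)
    sel = np.concatenate([errp_idx[:n_keep] if len(errp_idx) > n_keep else errp_idx,
                          non_kept])
    rng.shuffle(sel)
    return epochs.subset(sel)


def replace_data(epochs: EpochSet, data: np.ndarray) -> EpochSet:
    return EpochSet(
        data, epochs.labels.copy(), epochs.window_ms, epochs.fs_hz,
        list(epochs.channel_labels), epochs.participant_id, epochs.day_id,
        epochs.trial_indices.copy(),
    )


def preprocess_session(
    recording: Recording, config: PreprocessConfig | None = None, seed: int = 0
) -> tuple[EpochSet, PreprocessLog]:
    """Run the full chain on one session; returns epochs plus exclusion log."""
    config = config or PreprocessConfig()
    filtered = bandpass_filter(recording, config.band_hz, config.filter_order)
    bad = detect_bad_channels(filtered, config.bad_channel_sd_k)
    epochs = extract_epochs(filtered, config.epoch_window_ms, exclude_channels=bad)
    n_trials = epochs.n_epochs
    kept = reject_artifact_epochs(epochs, config.reject_amp_uV)
    n_rejected = n_trials - kept.n_epochs
    kept = normalize_epochs(kept)
    counts = kept.class_counts()
    out = balance_classes(kept, seed) if config.balance else kept
    log = PreprocessLog(
        recording.participant_id, recording.day_id, bad, n_trials, n_rejected,
        counts["ErrP"], counts["NonErrP"], out.n_epochs,
    )
    return out, log
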