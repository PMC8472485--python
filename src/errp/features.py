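"""Classifier input representations.

Two representations of a feedback-locked epoch are supported: the waveform
downsampled to 50 Hz by plain decimation (the 0.05-10 Hz band-pass already
guarantees the Nyquist condition at 25 Hz), and the entire epoch flattened.
No amplitude standardization is applied; features stay in microvolts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .preprocess import EpochSet

__all__ = ["FeatureMatrix", "downsample_features", "flatten_epochs", "build_features"]


@dataclass
class FeatureMatrix:
    """Trials x features with a provenance map back to (channel, time).

    Columns are channel-major: all retained samples of channel 0, then
    channel 1, etc.  ``feature_map[j]`` gives the (channel label, time in ms
    relative to feedback) of column j.
    """

    X: np.ndarray
    labels: np.ndarray
    feature_map: list[tuple[str, float]]
    representation: str  # "downsampled-50Hz" | "full-epoch"
    source_fs_hz: float

    def __post_init__(self) -> None:
        if self.X.shape[1] != len(self.feature_map):
            raise ValueError("feature_map length must equal the column count")
        if self.X.shape[0] != len(self.labels):
            raise ValueError("label count must equal the row count")

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


def _make_map(epochs: EpochSet, sample_idx: np.ndarray) -> list[tuple[str, float]]:
    t0 = epochs.window_ms[0]
    times = t0 + sample_idx / epochs.fs_hz * 1000.0
    return [(ch, float(t)) for ch in epochs.channel_labels for t in times]


def downsample_features(
    epochs: EpochSet, target_hz: float = 50.0, offset: int = 0,
    band_hz: tuple[float, float] | None = None,
) -> FeatureMatrix:
    """Temporal waveform features: every (fs/target)-th sample, from ``offset``.

    Requires an integer decimation factor.  If ``band_hz`` is given and its
    upper edge exceeds target_hz/2, a warning is raised because plain
    decimation would alias.
    """
    factor = epochs.fs_hz / target_hz
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError(
            f"sampling rate {epochs.fs_hz} Hz is not an integer multiple of {target_hz} Hz"
        )
    factor = int(round(factor))
    if not 0 <= offset < factor:
        raise ValueError("offset must lie in [0, decimation factor)")
    if band_hz is not None and band_hz[1] > target_hz / 2:
        warnings.warn(
            f"band upper edge {band_hz[1]} Hz exceeds {target_hz / 2} Hz; "
            "plain decimation will alias", stacklevel=2,
        )
    sample_idx = np.arange(offset, epochs.n_samples, factor)
    data = epochs.data[:, :, sample_idx]
    X = data.reshape(epochs.n_epochs, -1)
    name = f"downsampled-{target_hz:g}Hz"
    return FeatureMatrix(X, epochs.labels.copy(), _make_map(epochs, sample_idx),
                         name, epochs.fs_hz)


def flatten_epochs(epochs: EpochSet) -> FeatureMatrix:
    """Entire-epoch representation: channels x samples flattened per trial."""
    sample_idx = np.arange(epochs.n_samples)
    X = epochs.data.reshape(epochs.n_epochs, -1)
    return FeatureMatrix(X, epochs.labels.copy(), _make_map(epochs, sample_idx),
                         "full-epoch", epochs.fs_hz)


def build_features(epochs: EpochSet, representation: str, target_hz: float = 50.0) -> FeatureMatrix:
    """Dispatch on the classifier input representation name."""
    if representation in ("downsampled-50Hz", "features"):
        return downsample_features(epochs, target_hz)
    if representation in ("full-epoch", "epoch"):
        return flatten_epochs(epochs)
    raise ValueError(f"unknown representation {representation!r}")
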