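"""Electrode montage utilities.

The default montage is the 37-channel fronto-central/centro-parietal subset of
the 10-10 system that covers the sensorimotor cortex: AF3-4, Fz, F1-6, FCz,
FC1-6, Cz, C1-6, CPz, CP1-6, Pz, P1-6.  Feedback-locked error potentials are
maximal over fronto-central sites, so simulated scalp topographies are centred
on FCz by default.
"""

from __future__ import annotations

import numpy as np

__all__ = ["default_montage", "channel_positions", "spatial_weights"]

# anterior -> posterior row ordering of the 10-10 rows used here
_ROWS = ("AF", "F", "FC", "C", "CP", "P")
_ROW_Y = {"AF": 2.5, "F": 2.0, "FC": 1.0, "C": 0.0, "CP": -1.0, "P": -2.0}


def default_montage() -> list[str]:
    """The 37 sensorimotor 10-10 channel labels, anterior to posterior.

    Within a row the midline channel comes first, then left/right pairs in
    increasing distance from the midline (Fz, F1, F2, F3, F4, F5, F6).
    """
    labels = ["AF3", "AF4"]
    for row in ("F", "FC", "C", "CP", "P"):
        labels.append(f"{row}z")
        labels.extend(f"{row}{i}" for i in range(1, 7))
    return labels


def _label_xy(label: str) -> tuple[float, float]:
    row = label.rstrip("z0123456789")
    if row not in _ROW_Y:
        raise ValueError(f"unknown 10-10 row for channel {label!r}")
    suffix = label[len(row):]
    if suffix == "z":
        x = 0.0
    else:
        n = int(suffix)
        # odd indices are left hemisphere, even are right; distance grows
        # with ceil(n/2) in unit steps
        step = (n + 1) // 2
        x = -step if n % 2 == 1 else step
    return x, _ROW_Y[row]


def channel_positions(labels: list[str]) -> np.ndarray:
    """Approximate flattened scalp coordinates, one (x, y) row per label.

    Units are inter-electrode grid steps of the 10-10 system; sufficient for
    distance-based spatial weighting, not for source analysis.
    """
    return np.array([_label_xy(lab) for lab in labels], dtype=float)


def spatial_weights(labels: list[str], center: str = "FCz", rho: float = 2.0) -> np.ndarray:
    """Gaussian scalp weighting exp(-d^2 / (2 rho^2)) around ``center``.

    The weight is 1 at the centre channel and decays with grid distance;
    ``rho`` is the decay scale in grid steps.
    """
    if rho <= 0:
        raise ValueError("rho must be positive")
    pos = channel_positions(labels)
    cx, cy = _label_xy(center)
    d2 = (pos[:, 0] - cx) ** 2 + (pos[:, 1] - cy) ** 2
    return np.exp(-d2 / (2.0 * rho**2))
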