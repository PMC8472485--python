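"""Calibration schemes, chance level, grand averages, and correlations.

Three calibration schemes mirror how an ErrP decoder would be deployed:
within-day (stratified 10-fold cross-validation inside one session),
between-day (train on one day's session, test on the other, both directions),
and across-participant (leave-one-participant-out over a cohort).  Accuracy
is the trial-level fraction correct; the chance level is the smallest
accuracy whose binomial tail probability under random guessing is at or
below the significance level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .features import build_features
from .mlp import MLPArchitecture, train_mlp, predict_mlp
from .preprocess import ERRP, NONERRP, EpochSet
from .slda import train_slda, predict_slda

__all__ = [
    "METHODS",
    "ClassifierSpec",
    "EvalResult",
    "within_day_cv",
    "between_day",
    "across_participant_lopo",
    "chance_level",
    "grand_average",
    "correlate",
]

logger = logging.getLogger(__name__)

METHODS = ("mlp-features", "mlp-epoch", "slda-features")


@dataclass(frozen=True)
class ClassifierSpec:
    """Which classifier to run and on which input representation.

    ``mlp-features``: 50 Hz waveform features into the SCG-trained MLP.
    ``mlp-epoch``:    the entire epoch into the same MLP.
    ``slda-features``: 50 Hz waveform features into shrinkage LDA.
    """

    method: str = "slda-features"
    hidden_sizes: tuple[int, ...] = (100, 50, 25)
    max_iterations: int = 200
    feature_hz: float = 50.0
    slda_gamma: float | None = None  # None => analytic Ledoit-Wolf
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")

    @property
    def representation(self) -> str:
        return "full-epoch" if self.method == "mlp-epoch" else "downsampled-50Hz"


@dataclass
class EvalResult:
    """Outcome of one calibration scheme for one classifier spec."""

    scheme: str  # "within-day" | "between-day" | "across-participant"
    method: str
    unit_ids: list[str]  # fold / direction / held-out participant
    accuracies: np.ndarray
    n_test: np.ndarray
    chance: float
    seed: int = 0

    @property
    def mean(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def se(self) -> float:
        if len(self.accuracies) < 2:
            return 0.0
        return float(np.std(self.accuracies, ddof=1) / np.sqrt(len(self.accuracies)))


def _features_for(epochs: EpochSet, spec: ClassifierSpec):
    return build_features(epochs, spec.representation, spec.feature_hz)


def fit_predict(train: EpochSet, test: EpochSet, spec: ClassifierSpec) -> float:
    """Train per spec on ``train`` epochs and return accuracy on ``test``."""
    ftr = _features_for(train, spec)
    fte = _features_for(test, spec)
    if spec.method == "slda-features":
        model = train_slda(ftr.X, ftr.labels, spec.slda_gamma)
        pred = predict_slda(model, fte.X)
    else:
        arch = MLPArchitecture(
            input_size=ftr.n_features, hidden_sizes=spec.hidden_sizes,
            max_iterations=spec.max_iterations,
            validation_checks=spec.max_iterations, seed=spec.seed,
        )
        model = train_mlp(ftr.X, ftr.labels, arch)
        _, pred = predict_mlp(model, fte.X)
    return float(np.mean(pred == fte.labels))


def _stratified_folds(labels: np.ndarray, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Disjoint covering folds with class proportions preserved per fold."""
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        for j, i in enumerate(idx):
            folds[j % k].append(int(i))
    return [np.sort(np.array(f)) for f in folds]


def within_day_cv(epochs: EpochSet, spec: ClassifierSpec, k: int = 10, seed: int = 0) -> EvalResult:
    """Stratified k-fold cross-validation within a single session."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if epochs.n_epochs < k:
        raise ValueError("fewer epochs than folds")
    rng = np.random.default_rng(seed)
    folds = _stratified_folds(epochs.labels, k, rng)
    accs, ns = [], []
    all_idx = np.arange(epochs.n_epochs)
    for fold in folds:
        train_idx = np.setdiff1d(all_idx, fold)
        accs.append(fit_predict(epochs.subset(train_idx), epochs.subset(fold), spec))
        ns.append(len(fold))
    total = int(np.sum(ns))
    return EvalResult(
        "within-day", spec.method, [f"fold{j + 1}" for j in range(k)],
        np.array(accs), np.array(ns), chance_level(total), seed,
    )


def _common_channels(sets: list[EpochSet]) -> list[str]:
    common = [lab for lab in sets[0].channel_labels
              if all(lab in s.channel_labels for s in sets[1:])]
    if any(len(common) < len(s.channel_labels) for s in sets):
        logger.info("restricting to %d common channels", len(common))
    return common


def between_day(train: EpochSet, test: EpochSet, spec: ClassifierSpec) -> EvalResult:
    """Train on one day's session, test on the other day's (one direction)."""
    if test.n_epochs == 0:
        raise ValueError("test set is empty")
    common = _common_channels([train, test])
    tr = train.select_channels(common)
    te = test.select_channels(common)
    acc = fit_predict(tr, te, spec)
    unit = f"{train.day_id}->{test.day_id}"
    return EvalResult(
        "between-day", spec.method, [unit], np.array([acc]),
        np.array([te.n_epochs]), chance_level(te.n_epochs), spec.seed,
    )


def across_participant_lopo(cohort: list[EpochSet], spec: ClassifierSpec) -> EvalResult:
    """Leave-one-participant-out over one day's sessions.

    Each participant's balanced epochs join the training pool unweighted;
    channels are restricted to the cohort-wide intersection.
    """
    if len(cohort) < 2:
        raise ValueError("need at least 2 participants")
    common = _common_channels(cohort)
    sets = [s.select_channels(common) for s in cohort]
    accs, ns, units = [], [], []
    for i, held_out in enumerate(sets):
        rest = [s for j, s in enumerate(sets) if j != i]
        pooled = EpochSet(
            np.concatenate([s.data for s in rest]),
            np.concatenate([s.labels for s in rest]),
            held_out.window_ms, held_out.fs_hz, common,
            participant_id="pooled", day_id=held_out.day_id,
            trial_indices=np.arange(sum(s.n_epochs for s in rest)),
        )
        accs.append(fit_predict(pooled, held_out, spec))
        ns.append(held_out.n_epochs)
        units.append(held_out.participant_id)
    mean_n = int(np.round(np.mean(ns)))
    return EvalResult(
        "across-participant", spec.method, units, np.array(accs),
        np.array(ns), chance_level(mean_n), spec.seed,
    )


def chance_level(n_test: int, n_classes: int = 2, alpha: float = 0.05) -> float:
    """Smallest accuracy significantly above guessing at level ``alpha``.

    The smallest k/n_test with P(Binomial(n_test, 1/n_classes) >= k) <= alpha.
    Returns 1.0 (with a warning) when even a perfect score is not significant.
    """
    if n_test < 1:
        raise ValueError("n_test must be >= 1")
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    p = 1.0 / n_classes
    ks = np.arange(n_test + 1)
    tails = stats.binom.sf(ks - 1, n_test, p)  # P(X >= k)
    ok = np.flatnonzero(tails <= alpha)
    if len(ok) == 0:
        logger.warning("no accuracy on %d trials is significant at alpha=%g", n_test, alpha)
        return 1.0
    return float(ok[0] / n_test)


def grand_average(
    epoch_sets: list[EpochSet], channel: str, klass: str
) -> tuple[np.ndarray, np.ndarray]:
    """Grand mean and standard error across participants' mean waveforms.

    For each participant, the given channel's epochs of the given class are
    averaged; the grand average is the mean of those participant means and
    the SE their sample SD divided by sqrt(participants).  Participants
    lacking the channel or the class are skipped with a log message.
    """
    code = {"NonErrP": NONERRP, "ErrP": ERRP}[klass]
    per_participant = []
    for s in epoch_sets:
        if channel not in s.channel_labels:
            logger.info("%s: channel %s absent, skipped", s.participant_id, channel)
            continue
        ci = s.channel_labels.index(channel)
        rows = s.data[s.labels == code, ci, :]
        if len(rows) == 0:
            logger.info("%s: no %s epochs, skipped", s.participant_id, klass)
            continue
        per_participant.append(rows.mean(axis=0))
    if not per_participant:
        raise ValueError(f"no participant provides channel {channel!r} with {klass} epochs")
    arr = np.stack(per_participant)
    mean = arr.mean(axis=0)
    if arr.shape[0] < 2:
        return mean, np.zeros_like(mean)
    se = arr.std(axis=0, ddof=1) / np.sqrt(arr.shape[0])
    return mean, se


def correlate(x: np.ndarray, y: np.ndarray, method: str = "pearson") -> tuple[float, float]:
    """Pearson or Spearman correlation with a two-sided p-value.

    Ties in the Spearman ranks are handled by average ranks.  Raises on
    zero variance in either input (the coefficient is undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("inputs must have equal length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    if method == "pearson":
        res = stats.pearsonr(x, y)
    elif method == "spearman":
        res = stats.spearmanr(x, y)
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    return float(res.statistic), float(res.pvalue)
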