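"""Readers and writers for recordings, epochs, features, and configs.

Continuous recordings are stored as a directory containing ``signal.npz``
(channels x samples, microvolts), ``events.csv`` (columns: sample_index,
time_s, code), and ``recording.json`` (channel labels, sampling rate, ids).
Epoch sets use the same pattern (array + JSON sidecar); feature matrices
serialize to CSV with one row per trial and the (channel, time) provenance
in the header.  Configs are YAML or JSON.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
import yaml

from .features import FeatureMatrix
from .preprocess import EpochSet
from .simulate import Recording

__all__ = [
    "save_recording", "load_recording",
    "save_epochs", "load_epochs",
    "save_features", "load_config",
    "save_mlp", "load_mlp", "save_slda", "load_slda",
    "save_cohort_manifest",
]


def save_recording(recording: Recording, directory: str | Path) -> Path:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(d / "signal.npz", signal=recording.signal.astype(np.float32))
    with open(d / "events.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["sample_index", "time_s", "code"])
        for sample, code in recording.events:
            w.writerow([sample, f"{sample / recording.fs_hz:.6f}", code])
    meta = {
        "channel_labels": recording.channel_labels,
        "fs_hz": recording.fs_hz,
        "participant_id": recording.participant_id,
        "day_id": recording.day_id,
    }
    (d / "recording.json").write_text(json.dumps(meta, indent=2))
    return d


def load_recording(directory: str | Path) -> Recording:
    d = Path(directory)
    meta = json.loads((d / "recording.json").read_text())
    signal = np.load(d / "signal.npz")["signal"].astype(float)
    events = []
    with open(d / "events.csv", newline="") as fh:
        for row in csv.DictReader(fh):
            events.append((int(row["sample_index"]), row["code"]))
    return Recording(meta["channel_labels"], meta["fs_hz"], signal, events,
                     meta["participant_id"], meta["day_id"])


def save_epochs(epochs: EpochSet, directory: str | Path) -> Path:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(d / "epochs.npz", data=epochs.data.astype(np.float32),
                        labels=epochs.labels, trial_indices=epochs.trial_indices)
    meta = {
        "window_ms": list(epochs.window_ms),
        "fs_hz": epochs.fs_hz,
        "channel_labels": epochs.channel_labels,
        "participant_id": epochs.participant_id,
        "day_id": epochs.day_id,
    }
    (d / "epochs.json").write_text(json.dumps(meta, indent=2))
    return d


def load_epochs(directory: str | Path) -> EpochSet:
    d = Path(directory)
    meta = json.loads((d / "epochs.json").read_text())
    arrs = np.load(d / "epochs.npz")
    return EpochSet(
        arrs["data"].astype(float), arrs["labels"], tuple(meta["window_ms"]),
        meta["fs_hz"], meta["channel_labels"], meta["participant_id"],
        meta["day_id"], arrs["trial_indices"],
    )


def save_features(features: FeatureMatrix, path: str | Path) -> Path:
    path = Path(path)
    header = ["label"] + [f"{ch}@{t:g}ms" for ch, t in features.feature_map]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(header)
        for lab, row in zip(features.labels, features.X):
            w.writerow([int(lab)] + [f"{v:.6g}" for v in row])
    return path


def load_config(path: str | Path) -> dict:
    """YAML or JSON experiment/simulator configuration."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


def save_cohort_manifest(recordings: list[Recording], directory: str | Path,
                         paths: list[Path]) -> Path:
    d = Path(directory)
    entries = [
        {"participant_id": r.participant_id, "day_id": r.day_id,
         "path": str(p.relative_to(d)), "fs_hz": r.fs_hz,
         "n_channels": len(r.channel_labels), "n_samples": r.n_samples}
        for r, p in zip(recordings, paths)
    ]
    out = d / "cohort.json"
    out.write_text(json.dumps({"recordings": entries}, indent=2))
    return out


def save_mlp(model, directory: str | Path) -> Path:
    """MLP model: architecture/metadata JSON + weight arrays + loss-curve CSV."""
    from dataclasses import asdict

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    arch = asdict(model.architecture)
    arch["hidden_sizes"] = list(arch["hidden_sizes"])
    (d / "model.json").write_text(json.dumps({
        "kind": "mlp", "architecture": arch,
        "termination": model.training_record.termination,
    }, indent=2))
    arrays = {}
    for i, (W, b) in enumerate(zip(model.weights, model.biases)):
        arrays[f"W{i}"] = W
        arrays[f"b{i}"] = b
    np.savez_compressed(d / "weights.npz", **arrays)
    with open(d / "training_record.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["iteration", "loss"])
        for i, loss in enumerate(model.training_record.losses):
            w.writerow([i, f"{loss:.17g}"])
    return d


def load_mlp(directory: str | Path):
    from .mlp import MLPArchitecture, MLPModel
    from .scg import ScgRecord

    d = Path(directory)
    meta = json.loads((d / "model.json").read_text())
    arch_dict = meta["architecture"]
    arch_dict["hidden_sizes"] = tuple(arch_dict["hidden_sizes"])
    arch = MLPArchitecture(**arch_dict)
    arrs = np.load(d / "weights.npz")
    n_layers = len(arch.layer_sizes) - 1
    weights = [arrs[f"W{i}"] for i in range(n_layers)]
    biases = [arrs[f"b{i}"] for i in range(n_layers)]
    losses = []
    with open(d / "training_record.csv", newline="") as fh:
        for row in csv.DictReader(fh):
            losses.append(float(row["loss"]))
    record = ScgRecord(losses=losses, termination=meta["termination"])
    return MLPModel(arch, weights, biases, record)


def save_slda(model, directory: str | Path) -> Path:
    """sLDA model: gamma/priors/bias JSON + mean and covariance arrays."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    (d / "model.json").write_text(json.dumps({
        "kind": "slda", "gamma": model.gamma, "bias": model.bias,
        "priors": list(model.priors), "n_features": model.n_features,
    }, indent=2))
    np.savez_compressed(d / "weights.npz", mean_nonerrp=model.mean_nonerrp,
                        mean_errp=model.mean_errp, covariance=model.covariance,
                        w=model.w)
    return d


def load_slda(directory: str | Path):
    from .slda import SLDAModel

    d = Path(directory)
    meta = json.loads((d / "model.json").read_text())
    arrs = np.load(d / "weights.npz")
    return SLDAModel(arrs["mean_nonerrp"], arrs["mean_errp"], arrs["covariance"],
                     meta["gamma"], arrs["w"], meta["bias"],
                     tuple(meta["priors"]))
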