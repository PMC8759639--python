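"""Readers/writers for epochs, lead fields and cross-validation reports.

The canonical interchange container is a small HDF5 layout:

    /data           float64, trials x channels x samples (microvolts)
    /labels         int, per-trial class
    /subject_ids    int, per-trial subject index
    /channel_names  UTF-8 strings
    attrs: sampling_rate (Hz), t0_offset (s)

Standard epoched-EEG objects (``mne.EpochsArray``) are supported as an
optional adapter when mne is importable.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .dataset import EpochSet
from .pipelines import CVReport, FoldResult
from .sloreta import LeadField

REPORT_SCHEMA_VERSION = 1

_REQUIRED_MEMBERS = ("data", "labels", "subject_ids", "channel_names")


def write_epochs(epochs: EpochSet, path: str | Path) -> Path:
    """Write an :class:`EpochSet` to the internal HDF5 container."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data)
        f.create_dataset("labels", data=epochs.labels)
        f.create_dataset("subject_ids", data=epochs.subject_ids)
        f.create_dataset("channel_names",
                         data=np.array(epochs.channel_names, dtype="S32"))
        f.attrs["sampling_rate"] = epochs.sampling_rate
        f.attrs["t0_offset"] = epochs.t0_offset
    return path


def read_epochs(path: str | Path, format: str = "internal-h5") -> EpochSet:
    """Read an :class:`EpochSet` (lossless round trip for internal-h5)."""
    path = Path(path)
    if format == "internal-h5":
        with h5py.File(path, "r") as f:
            missing = [m for m in _REQUIRED_MEMBERS if m not in f]
            if missing:
                raise KeyError(
                    f"malformed epochs container {path}: missing member(s) {missing}"
                )
            return EpochSet(
                data=f["data"][()],
                labels=f["labels"][()],
                subject_ids=f["subject_ids"][()],
                channel_names=tuple(n.decode() for n in f["channel_names"][()]),
                sampling_rate=float(f.attrs["sampling_rate"]),
                t0_offset=float(f.attrs["t0_offset"]),
            )
    if format == "ecosystem-epochs":
        return from_mne_epochs(path)
    raise ValueError(f"unknown format '{format}'")


# -- mne adapter (optional) -------------------------------------------------

def to_mne_epochs(epochs: EpochSet):
    """Convert to ``mne.EpochsArray`` (volts, per mne convention)."""
    import mne

    info = mne.create_info(list(epochs.channel_names), epochs.sampling_rate,
                           ch_types="eeg")
    events = np.column_stack([
        np.arange(epochs.n_trials) * epochs.n_samples,
        np.zeros(epochs.n_trials, dtype=int),
        epochs.labels,
    ])
    return mne.EpochsArray(epochs.data * 1e-6, info, events=events,
                           tmin=epochs.t0_offset,
                           event_id={"checkerboard": 0, "tunnel": 1}, verbose=False)


def from_mne_epochs(source, subject_ids: np.ndarray | None = None) -> EpochSet:
    """Build an :class:`EpochSet` from ``mne`` epochs (object or file path)."""
    import mne

    ep = source if isinstance(source, mne.BaseEpochs) else mne.read_epochs(
        str(source), verbose=False)
    data = ep.get_data(copy=True) * 1e6
    labels = ep.events[:, 2]
    if subject_ids is None:
        subject_ids = np.zeros(len(labels), dtype=int)
    return EpochSet(data=data, labels=labels, subject_ids=subject_ids,
                    channel_names=tuple(ep.ch_names),
                    sampling_rate=float(ep.info["sfreq"]),
                    t0_offset=float(ep.tmin))


# -- lead fields ------------------------------------------------------------

def write_leadfield(lf: LeadField, path: str | Path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("K", data=lf.K)
        f.create_dataset("voxel_positions", data=lf.voxel_positions)
        f.create_dataset("region_labels", data=np.asarray(lf.region_labels, dtype=int))
    return path


def read_leadfield(path: str | Path) -> LeadField:
    with h5py.File(path, "r") as f:
        for member in ("K", "voxel_positions", "region_labels"):
            if member not in f:
                raise KeyError(f"malformed lead-field container: missing '{member}'")
        return LeadField(K=f["K"][()], voxel_positions=f["voxel_positions"][()],
                         region_labels=f["region_labels"][()])


# -- reports ----------------------------------------------------------------

def write_report(report: CVReport, path: str | Path) -> Path:
    """Serialize a :class:`CVReport` to JSON (stable key order)."""
    pooled = report.pooled()
    payload = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "scheme": report.scheme,
        "pipeline": report.pipeline,
        "folds": [
            {
                "fold_id": f.fold_id,
                "test_index": f.test_index.tolist(),
                "y_true": f.y_true.tolist(),
                "y_pred": f.y_pred.tolist(),
                "scores": f.scores.tolist(),
                "accuracy": f.accuracy,
            }
            for f in report.folds
        ],
        "pooled": {
            "accuracy": pooled["accuracy"],
            "mcc": pooled["mcc"],
            "auc": pooled["auc"],
            "ap": pooled["ap"],
            "confusion": pooled["confusion"].tolist(),
            "roc": [list(map(float, xy)) for xy in zip(*pooled["roc"])],
            "pr": [list(map(float, xy)) for xy in zip(*pooled["pr"])],
        },
        "mean_accuracy": report.mean_accuracy,
        "sd_accuracy": report.sd_accuracy,
    }
    path = Path(path)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return path


def read_report(path: str | Path) -> CVReport:
    """Reload a report written by :func:`write_report`."""
    payload = json.loads(Path(path).read_text())
    if "schema_version" not in payload:
        raise KeyError("report file lacks schema_version")
    report = CVReport(scheme=payload["scheme"], pipeline=payload["pipeline"])
    for f in payload["folds"]:
        report.folds.append(FoldResult(
            fold_id=f["fold_id"],
            test_index=np.asarray(f["test_index"], dtype=int),
            y_true=np.asarray(f["y_true"], dtype=int),
            y_pred=np.asarray(f["y_pred"], dtype=int),
            scores=np.asarray(f["scores"], dtype=float),
        ))
    return report
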