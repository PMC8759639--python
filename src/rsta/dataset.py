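"""Labelled multi-subject epoched-EEG container.

The :class:`EpochSet` is the raw material of every pipeline stage: a
``(n_trials, n_channels, n_samples)`` tensor of microvolt traces with
per-trial class labels (0 = Checkerboard, 1 = Tunnel), per-trial subject
indices, ordered channel names and sampling metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np


@dataclass(frozen=True)
class EpochSet:
    """Epoched multichannel EEG with trial-level bookkeeping.

    Parameters
    ----------
    data : ndarray, shape (n_trials, n_channels, n_samples)
        Trial traces in microvolts.
    labels : ndarray of int, shape (n_trials,)
        Binary class per trial: 0 (Checkerboard) or 1 (Tunnel).
    subject_ids : ndarray of int, shape (n_trials,)
        Subject index per trial.
    channel_names : tuple of str
        Electrode names, ordered as the channel axis.
    sampling_rate : float
        Sampling frequency in Hz.
    t0_offset : float
        Time of the first sample, in seconds relative to stimulus onset
        (negative values mean pre-stimulus samples are present).
    """

    data: np.ndarray
    labels: np.ndarray
    subject_ids: np.ndarray
    channel_names: tuple[str, ...]
    sampling_rate: float
    t0_offset: float = 0.0

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        labels = np.asarray(self.labels, dtype=int)
        subject_ids = np.asarray(self.subject_ids, dtype=int)
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "subject_ids", subject_ids)
        object.__setattr__(self, "channel_names", tuple(self.channel_names))
        if data.ndim != 3:
            raise ValueError(f"data must be 3-D (trials, channels, samples), got {data.ndim}-D")
        n_trials, n_channels, _ = data.shape
        if labels.shape != (n_trials,):
            raise ValueError(f"labels length {labels.shape} does not match {n_trials} trials")
        if subject_ids.shape != (n_trials,):
            raise ValueError(f"subject_ids length {subject_ids.shape} does not match {n_trials} trials")
        if len(self.channel_names) != n_channels:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {n_channels} data channels"
            )
        if not np.all(np.isin(labels, (0, 1))):
            raise ValueError("labels must be binary (0 or 1)")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")

    # -- basic geometry -------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds relative to stimulus onset."""
        return self.t0_offset + np.arange(self.n_samples) / self.sampling_rate

    @property
    def subjects(self) -> np.ndarray:
        """Sorted unique subject indices."""
        return np.unique(self.subject_ids)

    # -- derived sets ----------------------------------------------------
    def with_data(self, data: np.ndarray, **meta) -> "EpochSet":
        """Return a copy with new trial data (and optionally new metadata)."""
        kwargs = dict(
            data=data,
            labels=self.labels,
            subject_ids=self.subject_ids,
            channel_names=self.channel_names,
            sampling_rate=self.sampling_rate,
            t0_offset=self.t0_offset,
        )
        kwargs.update(meta)
        return EpochSet(**kwargs)

    def take(self, idx: np.ndarray | Sequence[int]) -> "EpochSet":
        """Subset trials by index, keeping labels and subjects aligned."""
        idx = np.asarray(idx, dtype=int)
        return EpochSet(
            data=self.data[idx],
            labels=self.labels[idx],
            subject_ids=self.subject_ids[idx],
            channel_names=self.channel_names,
            sampling_rate=self.sampling_rate,
            t0_offset=self.t0_offset,
        )

    def equals(self, other: "EpochSet") -> bool:
        """Bit-exact equality of data and metadata."""
        return (
            self.data.shape == other.data.shape
            and np.array_equal(self.data, other.data)
            and np.array_equal(self.labels, other.labels)
            and np.array_equal(self.subject_ids, other.subject_ids)
            and self.channel_names == other.channel_names
            and self.sampling_rate == other.sampling_rate
            and self.t0_offset == other.t0_offset
        )
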