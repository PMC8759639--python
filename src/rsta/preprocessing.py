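"""Signal conditioning: band-pass filtering, baseline correction, cropping,
electrode subsetting and per-subject class balancing.

The canonical order for the visual-ERP task is: zero-phase 1-45 Hz
band-pass, baseline correction over the -500..0 ms pre-stimulus window,
crop to [0, 500) ms, select the 12-electrode montage, and balance the
96-vs-192 class counts per subject by randomized undersampling.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .dataset import EpochSet


def bandpass_filter(epochs: EpochSet, low_hz: float, high_hz: float,
                    order: int = 4) -> EpochSet:
    """Zero-phase Butterworth band-pass along the time axis.

    The filter is applied forward and backward (``sosfiltfilt``), so the
    passband has zero phase lag. Shape and metadata are preserved.
    """
    nyquist = epochs.sampling_rate / 2.0
    if not (0.0 < low_hz < high_hz < nyquist):
        raise ValueError(
            f"cut-offs must satisfy 0 < low ({low_hz}) < high ({high_hz}) "
            f"< Nyquist ({nyquist})"
        )
    sos = butter(order, [low_hz, high_hz], btype="bandpass", fs=epochs.sampling_rate,
                 output="sos")
    return epochs.with_data(sosfiltfilt(sos, epochs.data, axis=-1))


def baseline_correct(epochs: EpochSet, window: tuple[float, float] | None = None) -> EpochSet:
    """Subtract the per-trial, per-channel mean over ``window`` (seconds).

    Default window is the full pre-stimulus interval (t0_offset .. 0).
    Idempotent: correcting twice equals correcting once.
    """
    if window is None:
        window = (epochs.t0_offset, 0.0)
    t = epochs.times
    t_end = epochs.t0_offset + epochs.n_samples / epochs.sampling_rate
    if window[0] < epochs.t0_offset - 1e-9 or window[1] > t_end + 1e-9:
        raise ValueError(
            f"baseline window {window} outside epoch span "
            f"[{epochs.t0_offset}, {t_end}]"
        )
    mask = (t >= window[0] - 1e-12) & (t < window[1] - 1e-12)
    if window[0] == window[1] or not mask.any():
        raise ValueError(f"baseline window {window} contains no samples")
    baseline = epochs.data[:, :, mask].mean(axis=-1, keepdims=True)
    return epochs.with_data(epochs.data - baseline)


def crop(epochs: EpochSet, t_start: float, t_end: float) -> EpochSet:
    """Restrict the time axis to the half-open interval [t_start, t_end).

    Sample selection uses ``floor((t - t0) * rate)`` boundaries so that
    repeated cropping composes exactly.
    """
    if not t_start < t_end:
        raise ValueError(f"t_start ({t_start}) must be < t_end ({t_end})")
    rate = epochs.sampling_rate
    # indices of samples with time in [t_start, t_end); guard rounding
    i0 = int(np.ceil((t_start - epochs.t0_offset) * rate - 1e-9))
    i1 = int(np.ceil((t_end - epochs.t0_offset) * rate - 1e-9))
    i0 = max(i0, 0)
    i1 = min(i1, epochs.n_samples)
    if i1 <= i0:
        raise ValueError(f"crop to [{t_start}, {t_end}) leaves no samples")
    return epochs.with_data(
        epochs.data[:, :, i0:i1],
        t0_offset=epochs.t0_offset + i0 / rate,
    )


def select_channels(epochs: EpochSet, names: list[str] | tuple[str, ...]) -> EpochSet:
    """Subset and reorder channels to ``names``; data rows follow names."""
    names = tuple(names)
    missing = [n for n in names if n not in epochs.channel_names]
    if missing:
        raise KeyError(f"unknown channel name(s): {missing}")
    idx = [epochs.channel_names.index(n) for n in names]
    return epochs.with_data(epochs.data[:, idx, :], channel_names=names)


def balance_classes(epochs: EpochSet, seed: int) -> EpochSet:
    """Per-subject randomized undersampling of the majority class.

    For each subject independently, majority-class trials are randomly
    removed until the two class counts are equal. Minority-class trials
    are never touched and within-class trial order is preserved.
    Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    keep = np.zeros(epochs.n_trials, dtype=bool)
    for subj in epochs.subjects:
        subj_mask = epochs.subject_ids == subj
        counts = [int(np.sum(subj_mask & (epochs.labels == k))) for k in (0, 1)]
        if min(counts) == 0:
            raise ValueError(f"subject {subj} has trials from only one class")
        n_keep = min(counts)
        for k in (0, 1):
            idx = np.flatnonzero(subj_mask & (epochs.labels == k))
            if idx.size > n_keep:
                chosen = rng.choice(idx, size=n_keep, replace=False)
                chosen.sort()  # preserve within-class order
            else:
                chosen = idx
            keep[chosen] = True
    return epochs.take(np.flatnonzero(keep))
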