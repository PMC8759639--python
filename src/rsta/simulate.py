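"""Synthetic multi-subject two-class visual-ERP generator.

Emulates the statistical structure of a passive visual-stimulation
experiment: 15 subjects viewing Checkerboard (96 trials) or 3D-Tunnel
(192 trials) stimuli, recorded on 12 scalp electrodes. The Checkerboard
evokes a large monophasic P100 followed by a P220; the Tunnel evokes a
lower-amplitude biphasic response around 100-140 ms plus a P220. Both
responses are occipitally dominant.

Each trial is built as

    x_trial = A_s @ (class template with per-trial jitter) + noise

where ``A_s`` is a per-subject spatial mixing matrix (random channel
gains plus a small orthogonal perturbation), the template is a sum of
Gaussian-windowed bumps with an occipital-heavy topography, and the
noise is per-channel 1/f^gamma background EEG plus white sensor noise.
Per-subject latency offsets and gain factors make pooled single trials
much harder to separate than within-subject trials, while leaving the
class geometry intact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

from .dataset import EpochSet

#: The 12-electrode montage used for classification.
DEFAULT_CHANNELS: tuple[str, ...] = (
    "F3", "Fz", "F4", "C3", "Cz", "C4", "P3", "Pz", "P4", "O1", "Oz", "O2",
)


@dataclass(frozen=True)
class Bump:
    """One Gaussian-windowed ERP component.

    ``latency_ms`` is the peak latency after stimulus onset, ``width_ms``
    the Gaussian sigma, ``amplitude_uv`` the signed peak amplitude, and
    ``topography`` an optional per-channel weight vector (defaults to the
    config-wide occipital profile).
    """

    latency_ms: float
    width_ms: float
    amplitude_uv: float
    topography: tuple[float, ...] | None = None


@dataclass(frozen=True)
class NoiseSpec:
    """Background-EEG and sensor noise levels.

    ``spectral_exponent`` is gamma in the 1/f^gamma background spectrum;
    ``background_sd_uv`` the per-channel background SD; ``sensor_sd_uv``
    the white sensor-noise SD.
    """

    spectral_exponent: float = 1.0
    background_sd_uv: float = 4.0
    sensor_sd_uv: float = 1.0


@dataclass(frozen=True)
class SubjectVariability:
    """Between-subject heterogeneity of the evoked response.

    ``mixing_scale`` scales a random orthogonal perturbation of the
    channel mixing; ``gain_sd`` is the sigma of lognormal per-subject
    channel gains; ``amplitude_gain_sd`` the SD of a per-subject global
    response gain; ``latency_sd_ms`` the SD of a per-subject latency
    offset applied to every component.
    """

    mixing_scale: float = 0.7
    gain_sd: float = 0.9
    amplitude_gain_sd: float = 0.6
    latency_sd_ms: float = 50.0


@dataclass(frozen=True)
class TrialVariability:
    """Trial-to-trial jitter of the evoked response."""

    amplitude_jitter_sd: float = 0.3
    latency_jitter_sd_ms: float = 15.0


def _default_templates() -> dict[int, tuple[Bump, ...]]:
    # Checkerboard (class 0): high-amplitude monophasic P100 + P220.
    # Tunnel (class 1): smaller biphasic 100/140 ms pair + P220.
    return {
        0: (Bump(100.0, 30.0, 10.0), Bump(220.0, 40.0, 4.0)),
        1: (Bump(100.0, 25.0, -4.0), Bump(140.0, 25.0, 4.0), Bump(220.0, 40.0, 4.0)),
    }


def _default_topography(channels: tuple[str, ...]) -> tuple[float, ...]:
    # Occipital >> parietal > central/frontal gradient by electrode prefix.
    gains = {"O": 1.0, "P": 0.6, "C": 0.3, "F": 0.15}
    return tuple(gains.get(name[0].upper(), 0.3) for name in channels)


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one simulated experiment."""

    n_subjects: int = 15
    trials_per_class: tuple[int, int] = (96, 192)
    channels: tuple[str, ...] = DEFAULT_CHANNELS
    sampling_rate: float = 512.0
    epoch_window: tuple[float, float] = (-0.5, 0.5)
    templates: dict[int, tuple[Bump, ...]] = field(default_factory=_default_templates)
    topography_profile: tuple[float, ...] | None = None
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    subject_variability: SubjectVariability = field(default_factory=SubjectVariability)
    trial_variability: TrialVariability = field(default_factory=TrialVariability)
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "channels", tuple(self.channels))
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if any(n < 1 for n in self.trials_per_class):
            raise ValueError("trials_per_class entries must be >= 1")
        if not (self.epoch_window[0] < 0.0 < self.epoch_window[1]):
            raise ValueError("epoch_window must straddle the stimulus: start < 0 < end")
        if self.sampling_rate <= 0 or self.sampling_rate > 2048:
            raise ValueError("sampling_rate must be in (0, 2048] Hz")
        for spec in (self.noise.background_sd_uv, self.noise.sensor_sd_uv,
                     self.subject_variability.gain_sd,
                     self.subject_variability.amplitude_gain_sd,
                     self.subject_variability.latency_sd_ms,
                     self.subject_variability.mixing_scale,
                     self.trial_variability.amplitude_jitter_sd,
                     self.trial_variability.latency_jitter_sd_ms):
            if spec < 0:
                raise ValueError("all noise/variability SDs must be >= 0")
        post_ms = self.epoch_window[1] * 1000.0
        for class_id, bumps in self.templates.items():
            for b in bumps:
                if not (0.0 < b.latency_ms < post_ms):
                    raise ValueError(
                        f"class {class_id} bump latency {b.latency_ms} ms outside "
                        f"post-stimulus window (0, {post_ms}) ms"
                    )
                if b.topography is not None and len(b.topography) != len(self.channels):
                    raise ValueError("bump topography length must equal channel count")
        if (self.topography_profile is not None
                and len(self.topography_profile) != len(self.channels)):
            raise ValueError("topography_profile length must equal channel count")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def topography(self) -> np.ndarray:
        prof = self.topography_profile
        if prof is None:
            prof = _default_topography(self.channels)
        return np.asarray(prof, dtype=float)

    @property
    def times(self) -> np.ndarray:
        start, end = self.epoch_window
        n = int(round((end - start) * self.sampling_rate))
        return start + np.arange(n) / self.sampling_rate


def class_template(config: SimulationConfig, class_id: int,
                   latency_shift_ms: float = 0.0) -> np.ndarray:
    """Noiseless channels x samples template of one class.

    This is the ground truth that the grand average converges to (before
    subject mixing); used directly for the zero-noise single-subject
    limit of :func:`generate_epochs`.
    """
    t_ms = config.times * 1000.0
    topo_default = config.topography
    out = np.zeros((config.n_channels, t_ms.size))
    for bump in config.templates[class_id]:
        topo = (np.asarray(bump.topography, dtype=float)
                if bump.topography is not None else topo_default)
        wave = bump.amplitude_uv * np.exp(
            -0.5 * ((t_ms - bump.latency_ms - latency_shift_ms) / bump.width_ms) ** 2
        )
        out += topo[:, None] * wave[None, :]
    return out


def _one_over_f_noise(rng: np.random.Generator, shape: tuple[int, ...],
                      exponent: float, fs: float) -> np.ndarray:
    """Gaussian noise with a 1/f^exponent amplitude spectrum, unit SD."""
    n = shape[-1]
    white = rng.standard_normal(shape)
    if exponent == 0.0:
        return white
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    scale = np.ones_like(freqs)
    nonzero = freqs > 0
    scale[nonzero] = freqs[nonzero] ** (-exponent / 2.0)
    scale[0] = 0.0  # no DC drift
    shaped = np.fft.irfft(np.fft.rfft(white, axis=-1) * scale, n=n, axis=-1)
    sd = shaped.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return shaped / sd


def _subject_mixing(rng: np.random.Generator, n_channels: int,
                    sv: SubjectVariability) -> np.ndarray:
    """Per-subject spatial mixing: orthogonal perturbation times channel gains."""
    gains = np.exp(rng.normal(0.0, sv.gain_sd, size=n_channels)) if sv.gain_sd > 0 \
        else np.ones(n_channels)
    if sv.mixing_scale > 0:
        skew = rng.standard_normal((n_channels, n_channels))
        skew = (skew - skew.T) / np.sqrt(2.0 * n_channels)
        rot = expm(sv.mixing_scale * skew)
    else:
        rot = np.eye(n_channels)
    return rot @ np.diag(gains)


def generate_epochs(config: SimulationConfig) -> EpochSet:
    """Simulate a full multi-subject two-class epoched-EEG dataset.

    Deterministic for a fixed ``config.seed``. Trials are ordered by
    subject, then class 0 then class 1, preserving within-class order.
    """
    rng = np.random.default_rng(config.seed)
    sv, tv, noise = config.subject_variability, config.trial_variability, config.noise
    times = config.times
    n_samples = times.size
    n_ch = config.n_channels
    n0, n1 = config.trials_per_class

    data, labels, subjects = [], [], []
    for subj in range(config.n_subjects):
        mixing = _subject_mixing(rng, n_ch, sv)
        subj_gain = (1.0 + rng.normal(0.0, sv.amplitude_gain_sd)
                     if sv.amplitude_gain_sd > 0 else 1.0)
        subj_latency = (rng.normal(0.0, sv.latency_sd_ms)
                        if sv.latency_sd_ms > 0 else 0.0)
        for class_id, n_trials in ((0, n0), (1, n1)):
            for _ in range(n_trials):
                lat = subj_latency
                if tv.latency_jitter_sd_ms > 0:
                    lat += rng.normal(0.0, tv.latency_jitter_sd_ms)
                gain = subj_gain
                if tv.amplitude_jitter_sd > 0:
                    gain *= 1.0 + rng.normal(0.0, tv.amplitude_jitter_sd)
                trial = mixing @ (gain * class_template(config, class_id, lat))
                if noise.background_sd_uv > 0:
                    trial = trial + noise.background_sd_uv * _one_over_f_noise(
                        rng, (n_ch, n_samples), noise.spectral_exponent,
                        config.sampling_rate)
                if noise.sensor_sd_uv > 0:
                    trial = trial + noise.sensor_sd_uv * rng.standard_normal(
                        (n_ch, n_samples))
                data.append(trial)
                labels.append(class_id)
                subjects.append(subj)

    return EpochSet(
        data=np.stack(data),
        labels=np.asarray(labels),
        subject_ids=np.asarray(subjects),
        channel_names=config.channels,
        sampling_rate=config.sampling_rate,
        t0_offset=config.epoch_window[0],
    )


def desk_scale_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Reduced-size profile for fast evaluation runs.

    Six subjects, 48/96 trials per class and 128 Hz sampling keep every
    cross-validated analysis in the seconds-to-minutes range while
    preserving the statistical structure of the full-scale design
    (occipital topography, class morphology, between-subject
    variability). Orderings measured at this scale transfer to the
    full-scale configuration; absolute accuracies do not.
    """
    params = dict(n_subjects=6, trials_per_class=(48, 96), sampling_rate=128.0,
                  seed=seed)
    params.update(overrides)
    return SimulationConfig(**params)


# ---------------------------------------------------------------------------
# Source-space simulation (ground truth for the inverse-solution module)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SourceSimulation:
    """Sensor-space epochs plus the source-space ground truth behind them.

    ``source_timecourses`` has shape (trials, 3*M, samples) — three
    orthogonal dipole orientations per voxel; ``epochs.data`` equals the
    lead field applied to the sources plus the configured sensor noise.
    """

    epochs: EpochSet
    source_timecourses: np.ndarray
    leadfield: "LeadField"  # noqa: F821 - forward ref to rsta.sloreta
    active_voxel_ids: dict[int, list[int]]


def generate_source_epochs(config: SimulationConfig, n_voxels: int,
                           n_regions: int = 4,
                           cond_threshold: float = 1e6,
                           max_retries: int = 50) -> SourceSimulation:
    """Simulate epochs via an explicit random lead field.

    A well-conditioned random gain matrix ``K`` (channels x 3*n_voxels)
    projects class-specific dipole activity at designated voxels to the
    sensors; white sensor noise (``config.noise.sensor_sd_uv``) is added
    on top. Class 0 activity is planted at voxel 0, class 1 at voxel 1.
    Background-EEG noise is injected as random source activity at every
    voxel so that it, too, respects the forward model.
    """
    from .sloreta import LeadField

    if n_voxels < 2:
        raise ValueError("n_voxels must be >= 2 (one active voxel per class)")
    if config.n_channels < 3:
        raise ValueError("source simulation needs at least 3 channels")

    rng = np.random.default_rng(config.seed)
    n_ch = config.n_channels
    for _ in range(max_retries):
        K = rng.standard_normal((n_ch, 3 * n_voxels)) / np.sqrt(3 * n_voxels)
        if np.linalg.cond(K @ K.T) < cond_threshold:
            break
    else:
        raise RuntimeError(
            f"could not draw a lead field with cond(KK^T) < {cond_threshold:g} "
            f"in {max_retries} attempts"
        )

    positions = rng.uniform(-1.0, 1.0, size=(n_voxels, 3))
    region_labels = np.arange(n_voxels) % max(1, min(n_regions, n_voxels))
    leadfield = LeadField(K=K, voxel_positions=positions, region_labels=region_labels)

    times = config.times
    n_samples = times.size
    active = {0: [0], 1: [1]}
    # Fixed unit orientation per active voxel, drawn once.
    orientations = {v: rng.standard_normal(3) for v in (0, 1)}
    for v in orientations:
        orientations[v] /= np.linalg.norm(orientations[v])

    tv, noise = config.trial_variability, config.noise
    n0, n1 = config.trials_per_class
    sources, sensor, labels, subjects = [], [], [], []
    for subj in range(config.n_subjects):
        subj_latency = (rng.normal(0.0, config.subject_variability.latency_sd_ms)
                        if config.subject_variability.latency_sd_ms > 0 else 0.0)
        for class_id, n_trials in ((0, n0), (1, n1)):
            t_ms = times * 1000.0
            for _ in range(n_trials):
                lat = subj_latency
                if tv.latency_jitter_sd_ms > 0:
                    lat += rng.normal(0.0, tv.latency_jitter_sd_ms)
                gain = 1.0
                if tv.amplitude_jitter_sd > 0:
                    gain *= 1.0 + rng.normal(0.0, tv.amplitude_jitter_sd)
                wave = np.zeros(n_samples)
                for bump in config.templates[class_id]:
                    wave += bump.amplitude_uv * np.exp(
                        -0.5 * ((t_ms - bump.latency_ms - lat) / bump.width_ms) ** 2)
                J = np.zeros((3 * n_voxels, n_samples))
                voxel = active[class_id][0]
                J[3 * voxel:3 * voxel + 3] = gain * orientations[voxel][:, None] * wave
                if noise.background_sd_uv > 0:
                    J += noise.background_sd_uv * _one_over_f_noise(
                        rng, (3 * n_voxels, n_samples), noise.spectral_exponent,
                        config.sampling_rate)
                x = K @ J
                if noise.sensor_sd_uv > 0:
                    x = x + noise.sensor_sd_uv * rng.standard_normal((n_ch, n_samples))
                sources.append(J)
                sensor.append(x)
                labels.append(class_id)
                subjects.append(subj)

    epochs = EpochSet(
        data=np.stack(sensor),
        labels=np.asarray(labels),
        subject_ids=np.asarray(subjects),
        channel_names=config.channels,
        sampling_rate=config.sampling_rate,
        t0_offset=config.epoch_window[0],
    )
    return SourceSimulation(
        epochs=epochs,
        source_timecourses=np.stack(sources),
        leadfield=leadfield,
        active_voxel_ids=active,
    )
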