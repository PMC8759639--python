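"""Standardized low-resolution (sLORETA) distributed inverse solution.

Given a lead field K (channels x 3M, three orthogonal dipole
orientations per voxel), the minimum-norm estimate of source activity is

    J_hat(alpha) = T(alpha) X,   T(alpha) = K' (K K' + alpha I)^{-1}

and sLORETA standardizes each voxel's 3-vector by the corresponding
3x3 diagonal block Sigma_l of the model resolution matrix T(alpha) K:

    J_sloreta_l = Sigma_l^{-1/2} T(alpha)_l X .

In the noiseless single-source limit this standardization yields exact
(zero-error) localization of the active voxel, which is the property the
tests assert. Region-averaged activation time courses (the orientation
norm per voxel, averaged over atlas-region members) provide the
source-space input to the sensor-space classification pipeline.

Real head models (e.g. a template anatomy with a cortical parcellation)
can be supplied through the same :class:`LeadField` container; the
package itself only constructs synthetic lead fields.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg


@dataclass(frozen=True)
class LeadField:
    """Forward gain matrix with voxel geometry and atlas labels.

    K has shape (channels, 3*M); ``region_labels`` assigns each of the M
    voxels to an atlas region for averaging.
    """

    K: np.ndarray
    voxel_positions: np.ndarray
    region_labels: np.ndarray

    def __post_init__(self) -> None:
        K = np.asarray(self.K, dtype=float)
        object.__setattr__(self, "K", K)
        object.__setattr__(self, "voxel_positions", np.asarray(self.voxel_positions, dtype=float))
        object.__setattr__(self, "region_labels", np.asarray(self.region_labels))
        if K.ndim != 2 or K.shape[1] % 3 != 0:
            raise ValueError("lead field must be 2-D with column count divisible by 3")
        if not np.all(np.isfinite(K)):
            raise ValueError("lead field contains non-finite entries")
        if self.region_labels.shape[0] != self.n_voxels:
            raise ValueError("one region label per voxel required")

    @property
    def n_channels(self) -> int:
        return self.K.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.K.shape[1] // 3


@dataclass(frozen=True)
class InverseOperator:
    """sLORETA inverse: T(alpha) plus per-voxel standardization blocks."""

    T: np.ndarray                  # 3M x channels
    alpha: float
    blocks: np.ndarray             # M x 3 x 3 diagonal blocks of T K
    leadfield: LeadField

    @property
    def n_voxels(self) -> int:
        return self.blocks.shape[0]


@dataclass(frozen=True)
class SourceEstimate:
    """Standardized source time courses and per-voxel power."""

    timecourses: np.ndarray        # 3M x samples
    power: np.ndarray              # M x samples, squared orientation norm

    @property
    def n_voxels(self) -> int:
        return self.power.shape[0]

    def voxel_activation(self) -> np.ndarray:
        """Orientation-norm activation per voxel (M x samples)."""
        return np.sqrt(self.power)


@dataclass(frozen=True)
class RegionActivation:
    """Region-averaged activation time courses (R x samples)."""

    activation: np.ndarray
    region_ids: np.ndarray


def default_alpha(leadfield: LeadField) -> float:
    """Trace-scaled regularization default for noisy data."""
    K = leadfield.K
    return 1e-2 * np.trace(K @ K.T) / K.shape[0]


def make_inverse(leadfield: LeadField, alpha: float) -> InverseOperator:
    """Build T(alpha) = K'(KK' + alpha I)^{-1} and its resolution blocks."""
    if not alpha > 0:
        raise ValueError("alpha must be > 0")
    K = leadfield.K
    gram = K @ K.T + alpha * np.eye(K.shape[0])
    try:
        solve = scipy.linalg.cho_factor(gram)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise np.linalg.LinAlgError("KK' + alpha I is numerically singular") from exc
    T = scipy.linalg.cho_solve(solve, K).T           # 3M x E
    resolution = T @ K                                # 3M x 3M
    M = leadfield.n_voxels
    blocks = np.empty((M, 3, 3))
    for l in range(M):
        b = resolution[3 * l:3 * l + 3, 3 * l:3 * l + 3]
        blocks[l] = (b + b.T) / 2.0
    return InverseOperator(T=T, alpha=alpha, blocks=blocks, leadfield=leadfield)


def _block_invsqrt(block: np.ndarray, voxel: int, pseudo: bool) -> np.ndarray:
    evals, evecs = scipy.linalg.eigh(block)
    floor = 1e-12 * max(evals[-1], 1e-300)
    if evals[0] <= floor:
        if not pseudo:
            raise np.linalg.LinAlgError(
                f"standardization block of voxel {voxel} is singular "
                f"(min eigenvalue {evals[0]:.3e}); pass pseudo_inverse=True to "
                "use a pseudo-inverse instead"
            )
        inv = np.where(evals > floor, 1.0 / np.sqrt(np.maximum(evals, floor)), 0.0)
    else:
        inv = 1.0 / np.sqrt(evals)
    return (evecs * inv) @ evecs.T


def apply_inverse(inv: InverseOperator, X: np.ndarray,
                  pseudo_inverse: bool = False) -> SourceEstimate:
    """Standardized sLORETA estimate of sensor data X (channels x samples)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] != inv.T.shape[1]:
        raise ValueError(
            f"data has {X.shape[0] if X.ndim == 2 else '?'} channels, "
            f"inverse expects {inv.T.shape[1]}"
        )
    J = inv.T @ X                                     # unstandardized, 3M x T
    out = np.empty_like(J)
    M = inv.n_voxels
    for l in range(M):
        W = _block_invsqrt(inv.blocks[l], l, pseudo_inverse)
        out[3 * l:3 * l + 3] = W @ J[3 * l:3 * l + 3]
    power = out.reshape(M, 3, -1)
    power = np.einsum("vot,vot->vt", power, power)
    return SourceEstimate(timecourses=out, power=power)


def localize(est: SourceEstimate) -> int:
    """Index of the voxel with the largest time-summed standardized power."""
    return int(est.power.sum(axis=1).argmax())


def average_by_region(est: SourceEstimate, leadfield: LeadField) -> RegionActivation:
    """Mean orientation-norm activation over the voxels of each atlas region.

    Regions are ordered by sorted region id; an empty region is an error.
    """
    labels = leadfield.region_labels
    if labels.size != est.n_voxels:
        raise ValueError("lead field labels do not match estimate voxel count")
    activation = est.voxel_activation()
    region_ids = np.unique(labels)
    rows = []
    for rid in region_ids:
        members = np.flatnonzero(labels == rid)
        if members.size == 0:  # pragma: no cover - unique() precludes this
            raise ValueError(f"region {rid} has no member voxels")
        rows.append(activation[members].mean(axis=0))
    return RegionActivation(activation=np.vstack(rows), region_ids=region_ids)
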