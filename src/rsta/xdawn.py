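"""xDAWN spatial filtering and augmented-trial covariance estimation.

The xDAWN estimator finds, for each stimulus class k, spatial filters w
maximizing the generalized Rayleigh quotient

    w' P_k P_k' w / w' X X' w

where P_k is the class-k grand-average (the evoked-response prototype)
and X is the concatenation of every trial from both classes along time.
The F filters per class with the largest generalized eigenvalues
maximize the evoked-response signal-to-noise ratio of their class.

Each trial X_i is then represented by the augmented matrix

    Z~_i = [ W_0' P_0 ; W_1' P_1 ; W' X_i ]        (4F rows)

whose (optionally shrunk) covariance Sigma_i = Z~_i Z~_i' / T is the
SPD feature fed to the Riemannian tangent-space classifier. With the
canonical F = 3 this covariance is 12 x 12.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
from sklearn.covariance import LedoitWolf, OAS

from .dataset import EpochSet


@dataclass(frozen=True)
class EvokedPrototype:
    """Grand average of one class: channels x samples, in microvolts."""

    matrix: np.ndarray
    class_id: int
    n_trials_averaged: int

    def __post_init__(self) -> None:
        if self.n_trials_averaged < 1:
            raise ValueError("prototype must average at least one trial")


@dataclass(frozen=True)
class SpatialFilterBank:
    """Fitted xDAWN filters for a two-class problem.

    ``filters`` maps class id to a channels x F matrix (columns are unit-norm
    filters, descending eigenvalue order); ``eigenvalues`` maps class id to
    the matching generalized eigenvalues. ``aggregated`` stacks class-0 then
    class-1 filters into channels x 2F.
    """

    filters: dict[int, np.ndarray]
    eigenvalues: dict[int, np.ndarray]
    n_filters: int

    @property
    def aggregated(self) -> np.ndarray:
        return np.hstack([self.filters[0], self.filters[1]])


@dataclass(frozen=True)
class AugmentedTrial:
    """The 4F x samples stack [W0'P0; W1'P1; W'X_i]."""

    matrix: np.ndarray
    n_filters: int

    def __post_init__(self) -> None:
        if self.matrix.shape[0] != 4 * self.n_filters:
            raise ValueError(
                f"augmented trial has {self.matrix.shape[0]} rows, "
                f"expected 4F = {4 * self.n_filters}"
            )


@dataclass(frozen=True)
class SPDMatrix:
    """A symmetric (positive-definite for shrinkage estimators) matrix."""

    values: np.ndarray
    estimator: str = "empirical"
    shrinkage: float = 0.0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("SPDMatrix must be square")
        if np.abs(v - v.T).max() > 1e-10 * max(1.0, np.abs(v).max()):
            raise ValueError("SPDMatrix must be symmetric to 1e-10")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def min_eigenvalue(self) -> float:
        return float(scipy.linalg.eigvalsh(self.values)[0])

    def is_spd(self, tol: float = 0.0) -> bool:
        return self.min_eigenvalue() > tol


def class_average(epochs: EpochSet, class_id: int) -> EvokedPrototype:
    """Element-wise mean over the trials of one class (the class VEP)."""
    mask = epochs.labels == class_id
    n = int(mask.sum())
    if n == 0:
        raise ValueError(f"no trials with class {class_id}")
    return EvokedPrototype(matrix=epochs.data[mask].mean(axis=0),
                           class_id=class_id, n_trials_averaged=n)


def _concatenate_trials(epochs: EpochSet) -> np.ndarray:
    # channels x (n_trials * n_samples): the "entire signal" X
    return np.concatenate(list(epochs.data), axis=1)


def fit_xdawn(epochs: EpochSet, n_filters: int = 3,
              cond_threshold: float = 1e12, reg_eps: float = 1e-10) -> SpatialFilterBank:
    """Estimate per-class xDAWN filters by a generalized eigenproblem.

    For each class k, solves ``P_k P_k' w = lambda X X' w`` and keeps the
    eigenvectors with the ``n_filters`` largest eigenvalues. Both classes
    share the denominator XX' computed from the concatenation of all
    trials. The sign of each filter is fixed by making its
    largest-magnitude entry positive; ties between equal eigenvalues are
    broken by the ascending channel index of that entry.
    """
    if n_filters < 1:
        raise ValueError("n_filters must be >= 1")
    if n_filters > epochs.n_channels:
        raise ValueError(
            f"n_filters ({n_filters}) exceeds channel count ({epochs.n_channels})"
        )
    for k in (0, 1):
        if not np.any(epochs.labels == k):
            raise ValueError(f"class {k} absent; xDAWN needs both classes")

    X = _concatenate_trials(epochs)
    XXt = X @ X.T
    if np.linalg.cond(XXt) > cond_threshold:
        XXt = XXt + reg_eps * (np.trace(XXt) / XXt.shape[0]) * np.eye(XXt.shape[0])
    if np.linalg.cond(XXt) > 1e15:
        raise np.linalg.LinAlgError(
            "signal covariance XX' is numerically singular even after regularization"
        )

    filters: dict[int, np.ndarray] = {}
    eigenvalues: dict[int, np.ndarray] = {}
    for k in (0, 1):
        P = class_average(epochs, k).matrix
        evals, evecs = scipy.linalg.eigh(P @ P.T, XXt)
        # descending eigenvalues; stable tie-break by largest-entry channel index
        peak = np.abs(evecs).argmax(axis=0)
        order = np.lexsort((peak, -evals))[:n_filters]
        w = evecs[:, order]
        w = w / np.linalg.norm(w, axis=0, keepdims=True)
        signs = np.sign(w[np.abs(w).argmax(axis=0), np.arange(w.shape[1])])
        signs[signs == 0] = 1.0
        filters[k] = w * signs
        eigenvalues[k] = evals[order]
    return SpatialFilterBank(filters=filters, eigenvalues=eigenvalues,
                             n_filters=n_filters)


def augment_trial(trial: np.ndarray, bank: SpatialFilterBank,
                  prototypes: tuple[EvokedPrototype, EvokedPrototype]) -> AugmentedTrial:
    """Stack the filtered prototypes of both classes over the filtered trial."""
    trial = np.asarray(trial, dtype=float)
    W = bank.aggregated
    if trial.ndim != 2 or trial.shape[0] != W.shape[0]:
        raise ValueError(
            f"trial shape {trial.shape} incompatible with {W.shape[0]}-channel bank"
        )
    p0, p1 = prototypes
    if p0.matrix.shape != trial.shape or p1.matrix.shape != trial.shape:
        raise ValueError("prototype shapes must match the trial shape")
    rows = np.vstack([
        bank.filters[0].T @ p0.matrix,
        bank.filters[1].T @ p1.matrix,
        W.T @ trial,
    ])
    return AugmentedTrial(matrix=rows, n_filters=bank.n_filters)


def covariance(aug: AugmentedTrial | np.ndarray,
               estimator: str = "oas",
               shrinkage: float | None = None) -> SPDMatrix:
    """Covariance of the augmented-trial rows over time.

    ``empirical`` is the plain second-moment matrix Z Z' / T (no mean
    removal, divisor = number of time samples). ``ledoit_wolf`` and
    ``oas`` shrink it toward a scaled identity with a data-driven
    intensity, preserving the trace; ``shrinkage`` forces a fixed
    intensity in [0, 1] instead.
    """
    Z = aug.matrix if isinstance(aug, AugmentedTrial) else np.asarray(aug, dtype=float)
    if Z.ndim != 2 or Z.shape[1] < 2:
        raise ValueError("need a 2-D matrix with at least 2 time samples")
    n_t = Z.shape[1]
    emp = (Z @ Z.T) / n_t
    emp = (emp + emp.T) / 2.0

    if shrinkage is not None:
        if not 0.0 <= shrinkage <= 1.0:
            raise ValueError("shrinkage must lie in [0, 1]")
        mu = np.trace(emp) / emp.shape[0]
        vals = (1.0 - shrinkage) * emp + shrinkage * mu * np.eye(emp.shape[0])
        return SPDMatrix(values=vals, estimator=f"{estimator}(forced)",
                         shrinkage=float(shrinkage))

    if estimator == "empirical":
        return SPDMatrix(values=emp, estimator="empirical", shrinkage=0.0)
    if estimator in ("ledoit_wolf", "oas"):
        model = LedoitWolf(assume_centered=True) if estimator == "ledoit_wolf" \
            else OAS(assume_centered=True)
        model.fit(Z.T)  # samples = time points, features = rows
        vals = (model.covariance_ + model.covariance_.T) / 2.0
        out = SPDMatrix(values=vals, estimator=estimator,
                        shrinkage=float(model.shrinkage_))
        if not out.is_spd():
            raise np.linalg.LinAlgError(
                f"{estimator} covariance not positive definite"
            )
        return out
    raise ValueError(f"unknown estimator '{estimator}'")
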