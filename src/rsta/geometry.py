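"""Affine-invariant geometry of SPD matrices: Karcher mean and tangent space.

Covariance matrices live on the manifold of symmetric positive-definite
(SPD) matrices. Under the affine-invariant metric the distance is

    delta(A, B) = || logm(A^{-1/2} B A^{-1/2}) ||_F

and the Frechet/Karcher mean of a set is the point minimizing the mean
squared distance. Mapping every covariance to the tangent space at that
mean and half-vectorizing (sqrt(2) weight off-diagonal) yields Euclidean
vectors of dimension n(n+1)/2 whose norms equal Riemannian distances to
the reference — the feature space of the tangent-space classifier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .xdawn import SPDMatrix

_EIG_FLOOR = 1e-12


def _as_matrix(m: SPDMatrix | np.ndarray) -> np.ndarray:
    return m.values if isinstance(m, SPDMatrix) else np.asarray(m, dtype=float)


def _spd_eigh(m: np.ndarray, what: str) -> tuple[np.ndarray, np.ndarray]:
    evals, evecs = scipy.linalg.eigh((m + m.T) / 2.0)
    if evals[0] <= _EIG_FLOOR * max(1.0, evals[-1]):
        raise np.linalg.LinAlgError(
            f"{what}: matrix is not positive definite "
            f"(min eigenvalue {evals[0]:.3e})"
        )
    return evals, evecs


def sqrtm_spd(m: SPDMatrix | np.ndarray) -> np.ndarray:
    """Symmetric square root of an SPD matrix via eigendecomposition."""
    evals, evecs = _spd_eigh(_as_matrix(m), "sqrtm")
    return (evecs * np.sqrt(evals)) @ evecs.T


def invsqrtm_spd(m: SPDMatrix | np.ndarray) -> np.ndarray:
    evals, evecs = _spd_eigh(_as_matrix(m), "invsqrtm")
    return (evecs / np.sqrt(evals)) @ evecs.T


def logm_spd(m: SPDMatrix | np.ndarray) -> np.ndarray:
    evals, evecs = _spd_eigh(_as_matrix(m), "logm")
    return (evecs * np.log(evals)) @ evecs.T


def expm_sym(m: np.ndarray) -> np.ndarray:
    """Matrix exponential of a symmetric matrix (always SPD)."""
    evals, evecs = scipy.linalg.eigh((m + m.T) / 2.0)
    return (evecs * np.exp(evals)) @ evecs.T


def riemannian_distance(a: SPDMatrix | np.ndarray, b: SPDMatrix | np.ndarray) -> float:
    """Affine-invariant distance ||logm(A^{-1/2} B A^{-1/2})||_F."""
    isq = invsqrtm_spd(a)
    return float(np.linalg.norm(logm_spd(isq @ _as_matrix(b) @ isq), "fro"))


@dataclass(frozen=True)
class ReferencePoint:
    """Geometric (Karcher) mean of a training set of covariances."""

    matrix: np.ndarray
    iterations: int
    final_step_norm: float

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class TangentVector:
    """Half-vectorized tangent-space image of one SPD matrix."""

    values: np.ndarray
    reference_id: int  # id() of the ReferencePoint used

    def __len__(self) -> int:
        return self.values.size


def geometric_mean(matrices: list[SPDMatrix | np.ndarray], tol: float = 1e-8,
                   max_iter: int = 200) -> ReferencePoint:
    """Karcher mean under the affine-invariant metric.

    Fixed-point iteration: at the current estimate S, average the
    log-maps of all matrices in the tangent space at S and step along
    the mean (unit step size); stop when the Frobenius norm of the mean
    tangent update falls below ``tol``.
    """
    if not matrices:
        raise ValueError("geometric_mean needs a non-empty set")
    mats = [_as_matrix(m) for m in matrices]
    n = mats[0].shape[0]
    if any(m.shape != (n, n) for m in mats):
        raise ValueError("all matrices must share a common size")
    if len(mats) == 1:
        return ReferencePoint(matrix=mats[0].copy(), iterations=0, final_step_norm=0.0)

    S = np.mean(mats, axis=0)  # arithmetic-mean initialization
    step_norm = np.inf
    for it in range(1, max_iter + 1):
        sq, isq = sqrtm_spd(S), invsqrtm_spd(S)
        T = np.mean([logm_spd(isq @ m @ isq) for m in mats], axis=0)
        step_norm = float(np.linalg.norm(T, "fro"))
        S = sq @ expm_sym(T) @ sq
        S = (S + S.T) / 2.0
        if step_norm < tol:
            return ReferencePoint(matrix=S, iterations=it, final_step_norm=step_norm)
    raise RuntimeError(
        f"Karcher mean did not converge in {max_iter} iterations "
        f"(last step norm {step_norm:.3e})"
    )


def log_map(sigma: SPDMatrix | np.ndarray, ref: ReferencePoint) -> np.ndarray:
    """Riemannian logarithm of sigma at the reference point.

    Phi(Sigma) = S^{1/2} logm(S^{-1/2} Sigma S^{-1/2}) S^{1/2} with
    S = ref.matrix; the output is symmetric.
    """
    m = _as_matrix(sigma)
    if m.shape != ref.matrix.shape:
        raise ValueError("matrix and reference sizes differ")
    sq, isq = sqrtm_spd(ref.matrix), invsqrtm_spd(ref.matrix)
    out = sq @ logm_spd(isq @ m @ isq) @ sq
    return (out + out.T) / 2.0


def exp_map(phi: np.ndarray, ref: ReferencePoint) -> np.ndarray:
    """Inverse of :func:`log_map`: retract a tangent matrix to the manifold."""
    sq, isq = sqrtm_spd(ref.matrix), invsqrtm_spd(ref.matrix)
    return sq @ expm_sym(isq @ phi @ isq) @ sq


def vectorize_tangent(S: np.ndarray, ref: ReferencePoint,
                      atol: float = 1e-8) -> TangentVector:
    """Whitened upper-triangular half-vectorization of a tangent matrix.

    The tangent matrix S (output of :func:`log_map`) is whitened by the
    reference, ``ref^{-1/2} S ref^{-1/2}``, then vectorized with weight 1
    on the diagonal and sqrt(2) off-diagonal, so the Euclidean norm of
    the vector equals the Frobenius norm of the whitened matrix — i.e.
    the Riemannian distance when S is a log-map.
    """
    S = np.asarray(S, dtype=float)
    if np.abs(S - S.T).max() > atol * max(1.0, np.abs(S).max()):
        raise ValueError("tangent matrix is not symmetric")
    isq = invsqrtm_spd(ref.matrix)
    W = isq @ S @ isq
    W = (W + W.T) / 2.0
    n = W.shape[0]
    iu = np.triu_indices(n)
    weights = np.where(iu[0] == iu[1], 1.0, np.sqrt(2.0))
    return TangentVector(values=W[iu] * weights, reference_id=id(ref))


def project_set(matrices: list[SPDMatrix | np.ndarray],
                ref: ReferencePoint | str = "fit") -> tuple[list[TangentVector], ReferencePoint]:
    """Map a set of SPD matrices to tangent vectors at a common reference.

    With ``ref="fit"`` the reference is the geometric mean of this
    (training) set; a frozen :class:`ReferencePoint` projects held-out
    matrices without re-fitting (no leakage).
    """
    if not matrices:
        raise ValueError("project_set needs a non-empty set")
    if isinstance(ref, str):
        if ref != "fit":
            raise ValueError("ref must be a ReferencePoint or 'fit'")
        ref = geometric_mean(matrices)
    vectors = [vectorize_tangent(log_map(m, ref), ref) for m in matrices]
    return vectors, ref
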