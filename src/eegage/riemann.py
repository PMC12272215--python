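"""Bures-Wasserstein geometry on the SPD manifold.

Covariance matrices of narrow-band EEG live on the cone of symmetric
positive definite (SPD) matrices.  Linear models cannot consume SPD
matrices directly, so each matrix is mapped to the flat tangent space at
a reference point -- here the Bures-Wasserstein (optimal-transport)
barycenter of the training covariances.  The embedding used below has
the property that the Euclidean norm of the embedded vector equals the
Bures-Wasserstein distance to the reference, so ordinary ridge
regression on the embedded coordinates respects the manifold geometry
to first order.

All functions operate on plain ``numpy`` arrays and are deliberately
free of any EEG-specific structure; they apply to SPD matrices of any
dimension.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg


class BarycenterConvergenceError(RuntimeError):
    """Fixed-point iteration for the barycenter failed to converge.

    Carries the last iterate and the final Frobenius residual so callers
    can inspect (or accept) the partial result.
    """

    def __init__(self, last_iterate: np.ndarray, residual: float, max_iter: int):
        self.last_iterate = last_iterate
        self.residual = residual
        super().__init__(
            f"Bures-Wasserstein barycenter did not converge within {max_iter} "
            f"iterations (final Frobenius residual {residual:.3e})"
        )


def sym_sqrtm(mat: np.ndarray, inverse: bool = False) -> np.ndarray:
    """Symmetric (principal) square root of an SPD matrix via eigendecomposition.

    With ``inverse=True`` returns the inverse square root instead.
    Eigenvalues are floored at a tiny positive value to guard against
    numerically semi-definite input.
    """
    mat = np.asarray(mat, dtype=float)
    vals, vecs = linalg.eigh(mat)
    vals = np.maximum(vals, 1e-15)
    d = 1.0 / np.sqrt(vals) if inverse else np.sqrt(vals)
    return (vecs * d) @ vecs.T


def is_spd(mat: np.ndarray, tol: float = 1e-10) -> bool:
    """True if ``mat`` is symmetric with all eigenvalues > ``tol``."""
    mat = np.asarray(mat)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        return False
    if not np.allclose(mat, mat.T, atol=1e-8 * max(1.0, np.abs(mat).max())):
        return False
    return bool(linalg.eigvalsh(mat).min() > tol)


def bures_wasserstein_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Closed-form Bures-Wasserstein distance between two SPD matrices.

    d(A, B)^2 = tr(A) + tr(B) - 2 tr[(A^{1/2} B A^{1/2})^{1/2}],
    the 2-Wasserstein distance between centred Gaussians with the given
    covariances.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a_half = sym_sqrtm(a)
    cross = sym_sqrtm(a_half @ b @ a_half)
    d2 = np.trace(a) + np.trace(b) - 2.0 * np.trace(cross)
    return float(np.sqrt(max(d2, 0.0)))


def wasserstein_mean(
    mats: list[np.ndarray] | np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> np.ndarray:
    """Bures-Wasserstein barycenter of a set of SPD matrices.

    Runs the standard fixed-point iteration

        M <- M^{-1/2} [ mean_i (M^{1/2} S_i M^{1/2})^{1/2} ]^2 M^{-1/2}

    initialised at the Euclidean mean, stopping when the Frobenius norm
    of the update falls below ``tol``.

    Raises
    ------
    BarycenterConvergenceError
        if the residual is still above ``tol`` after ``max_iter`` steps.
    """
    mats = [np.asarray(m, dtype=float) for m in mats]
    if len(mats) == 0:
        raise ValueError("wasserstein_mean requires at least one SPD matrix")
    if len(mats) == 1:
        return mats[0].copy()

    current = np.mean(mats, axis=0)
    residual = np.inf
    for _ in range(max_iter):
        root = sym_sqrtm(current)
        inv_root = sym_sqrtm(current, inverse=True)
        inner = np.mean([sym_sqrtm(root @ m @ root) for m in mats], axis=0)
        updated = inv_root @ inner @ inner @ inv_root
        updated = 0.5 * (updated + updated.T)
        residual = float(np.linalg.norm(updated - current, ord="fro"))
        current = updated
        if residual < tol:
            return current
    raise BarycenterConvergenceError(current, residual, max_iter)


def _upper_vec(sym: np.ndarray) -> np.ndarray:
    """Vectorize a symmetric matrix to its d(d+1)/2 upper triangle.

    Off-diagonal entries are scaled by sqrt(2) so that the Euclidean
    norm of the vector equals the Frobenius norm of the matrix.
    """
    d = sym.shape[0]
    iu, ju = np.triu_indices(d)
    weights = np.where(iu == ju, 1.0, np.sqrt(2.0))
    return sym[iu, ju] * weights


def upper_vec_labels(dim: int, names: list[str] | None = None) -> list[str]:
    """Coordinate labels matching :func:`_upper_vec` ordering."""
    if names is None:
        names = [str(i) for i in range(dim)]
    iu, ju = np.triu_indices(dim)
    return [names[i] if i == j else f"{names[i]}|{names[j]}" for i, j in zip(iu, ju)]


@dataclass
class TangentPoint:
    """A reference point on the SPD manifold with cached embedding maps.

    ``gram_sqrt`` is the square root of the Gram matrix of the
    horizontal-space basis {E_a Ybar}, where {E_a} is the orthonormal
    symmetric-matrix basis; it turns symmetric-basis coefficients into
    coordinates whose Euclidean norm equals the Frobenius norm on the
    horizontal space (hence the Bures-Wasserstein distance).
    """

    mean: np.ndarray
    sqrt: np.ndarray
    inv_sqrt: np.ndarray
    gram_sqrt: np.ndarray

    @property
    def dim(self) -> int:
        return self.mean.shape[0]


def _horizontal_gram(ybar: np.ndarray) -> np.ndarray:
    """Gram matrix of the horizontal basis {E_a Ybar} under Frobenius."""
    d = ybar.shape[0]
    iu, ju = np.triu_indices(d)
    basis = np.zeros((iu.size, d, d))
    inv_sqrt2 = 1.0 / np.sqrt(2.0)
    for a, (i, j) in enumerate(zip(iu, ju)):
        if i == j:
            basis[a, i] = ybar[i]
        else:
            basis[a, i] = ybar[j] * inv_sqrt2
            basis[a, j] += ybar[i] * inv_sqrt2
    flat = basis.reshape(iu.size, -1)
    return flat @ flat.T


def tangent_point(mean: np.ndarray) -> TangentPoint:
    """Precompute the embedding maps at a reference SPD matrix."""
    mean = np.asarray(mean, dtype=float)
    root = sym_sqrtm(mean)
    return TangentPoint(
        mean=mean,
        sqrt=root,
        inv_sqrt=sym_sqrtm(mean, inverse=True),
        gram_sqrt=sym_sqrtm(_horizontal_gram(root)),
    )


def tangent_embed(sigma: np.ndarray, point: TangentPoint) -> np.ndarray:
    """Embed an SPD matrix in the Bures-Wasserstein tangent space at a reference.

    With Y the symmetric square root of ``sigma`` and Ybar that of the
    reference, the orthogonal alignment Q* minimising ||Y Q - Ybar||_F
    is applied.  The aligned difference decomposes as
    Y Q* - Ybar = S Ybar with S symmetric (it lies in the horizontal
    space of the square-root submersion), so its d(d+1)/2 coordinates
    in an orthonormal basis of that space capture it losslessly: the
    Euclidean norm of the returned vector equals the Bures-Wasserstein
    distance to the reference exactly.
    """
    sigma = np.asarray(sigma, dtype=float)
    if sigma.shape != point.mean.shape:
        raise ValueError(
            f"dimension mismatch: matrix is {sigma.shape}, "
            f"reference is {point.mean.shape}"
        )
    y = sym_sqrtm(sigma)
    # optimal orthogonal alignment: max_Q tr(Q^T Y^T Ybar) -> Q* = U V^T
    # from the SVD  Y^T Ybar = U D V^T
    u, _, vt = linalg.svd(y.T @ point.sqrt)
    q_star = u @ vt
    delta = y @ q_star - point.sqrt
    s = delta @ point.inv_sqrt
    s = 0.5 * (s + s.T)  # symmetric up to roundoff by construction
    return point.gram_sqrt @ _upper_vec(s)
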