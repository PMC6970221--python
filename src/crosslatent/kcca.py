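"""Regularized kernel CCA (linear kernel) in a reduced eigenbasis.

For centered views X, Y with linear kernels K_x = XX', K_y = YY', one effect
solves

    max_{alpha, beta}  alpha' K_x K_y beta
    s.t.  (1 - kappa_x) alpha' K_x^2 alpha + kappa_x alpha' K_x alpha = 1
          (1 - kappa_y) beta'  K_y^2 beta  + kappa_y beta'  K_y beta  = 1.

The two regularization parameters kappa in [0, 1] interpolate smoothly
between maximizing correlation (kappa = 0: the constraint normalizes the
score variance, classical CCA) and maximizing covariance (kappa = 1: the
constraint normalizes the primal weight norm, i.e. PLS).  Working in the
dual keeps the problem n x n regardless of feature counts.

Implementation: each kernel is eigendecomposed and rank-truncated; in that
basis both constraints become diagonal, so the problem reduces to a leading
singular pair of a small matrix — deterministic and exact at desk scale.
Successive effects come from projection deflation in primal space, with
kernels recomputed from the deflated data, mirroring the sparse-PLS loop.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .spls import DegenerateInputError

_RANK_TRUNCATION = 1e-10  # relative eigenvalue cutoff for the reduced basis


@dataclass(frozen=True)
class KccaParams:
    """Per-view interpolation parameters between CCA (0) and PLS (1), plus a
    jitter added to the constraint matrices for numerical solvability."""

    kappa_x: float
    kappa_y: float
    jitter: Optional[float] = None  # default 1e-9 * trace(K)/n, set at fit time

    def __post_init__(self) -> None:
        if not (0.0 <= self.kappa_x <= 1.0 and 0.0 <= self.kappa_y <= 1.0):
            raise ValueError("kappa parameters must lie in [0, 1]")
        if self.jitter is not None and self.jitter <= 0:
            raise ValueError("jitter must be positive")

    def as_dict(self) -> dict:
        return {"kappa_x": float(self.kappa_x), "kappa_y": float(self.kappa_y)}


@dataclass
class DualSolution:
    """Leading dual eigenpair: alpha, beta normalized so each view's
    regularized quadratic form equals 1, and the achieved objective rho."""

    alpha: np.ndarray
    beta: np.ndarray
    rho: float


@dataclass
class KernelBasis:
    """Eigendecomposition of one kernel, truncated at relative eigenvalue
    1e-10; reused across grid cells since it does not depend on kappa."""

    vectors: np.ndarray  # n x r
    eigenvalues: np.ndarray  # r, positive, descending
    trace: float

    @classmethod
    def from_kernel(cls, k: np.ndarray) -> "KernelBasis":
        k = np.asarray(k, dtype=float)
        if k.shape[0] != k.shape[1] or not np.allclose(k, k.T, atol=1e-8):
            raise ValueError("kernel must be a symmetric square matrix")
        evals, evecs = np.linalg.eigh(k)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        if evals[0] <= 0:
            raise DegenerateInputError("kernel has no positive eigenvalue")
        keep = evals > _RANK_TRUNCATION * evals[0]
        return cls(evecs[:, keep], evals[keep], float(np.trace(k)))


def linear_kernel(x: np.ndarray) -> np.ndarray:
    """Gram matrix K = XX' of a centered view."""
    x = np.asarray(x, dtype=float)
    return x @ x.T


def _constraint_diag(basis: KernelBasis, kappa: float, jitter: float) -> np.ndarray:
    s = basis.eigenvalues
    return (1.0 - kappa) * s**2 + kappa * s + jitter


def kcca_fit(
    k_x: np.ndarray,
    k_y: np.ndarray,
    params: KccaParams,
    basis_x: Optional[KernelBasis] = None,
    basis_y: Optional[KernelBasis] = None,
) -> DualSolution:
    """Solve the regularized dual problem for the leading effect.

    Precomputed :class:`KernelBasis` objects may be passed to amortize the
    eigendecompositions across a kappa grid.
    """
    bx = basis_x if basis_x is not None else KernelBasis.from_kernel(k_x)
    by = basis_y if basis_y is not None else KernelBasis.from_kernel(k_y)
    if bx.vectors.shape[0] != by.vectors.shape[0]:
        raise ValueError("kernels must share the sample dimension")

    n = bx.vectors.shape[0]
    jitter = params.jitter
    if jitter is None:
        jitter = 1e-9 * max(bx.trace, by.trace) / n

    # In the eigenbasis alpha = U_x a, the objective is a' S_x U_x' K_y V b
    # = a' S_x (U_x'U_y) S_y b and each constraint is diagonal.
    cross = (bx.vectors.T @ by.vectors) * np.outer(bx.eigenvalues, by.eigenvalues)
    dx = _constraint_diag(bx, params.kappa_x, jitter)
    dy = _constraint_diag(by, params.kappa_y, jitter)
    c = cross / np.sqrt(np.outer(dx, dy))
    uu, ss, vvt = np.linalg.svd(c, full_matrices=False)
    a = uu[:, 0] / np.sqrt(dx)
    b = vvt[0] / np.sqrt(dy)
    alpha = bx.vectors @ a
    beta = by.vectors @ b
    # deterministic sign: largest-magnitude entry of alpha positive
    j = int(np.argmax(np.abs(alpha)))
    if alpha[j] < 0:
        alpha, beta = -alpha, -beta
    return DualSolution(alpha, beta, float(ss[0]))


def recover_primal_weights(x: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Map a dual vector to the unit primal weight w = X'alpha / ||X'alpha||."""
    w = np.asarray(x, dtype=float).T @ np.asarray(alpha, dtype=float)
    norm = np.linalg.norm(w)
    if norm == 0.0:
        raise DegenerateInputError("dual vector maps to the zero primal weight")
    return w / norm


def kcca_deflate(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Projection deflation in primal space; kernels are recomputed from the
    deflated data. Identical contract to :func:`crosslatent.spls.deflate`."""
    from .spls import deflate

    return deflate(x, w)
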