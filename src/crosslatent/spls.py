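"""Sparse partial least squares by alternating soft-thresholded updates.

One latent effect is the rank-one problem

    max_{u, v}  u' X'Y v   s.t.  ||u||_2 = 1, ||u||_1 <= c_u,
                                 ||v||_2 = 1, ||v||_1 <= c_v,

the penalized-matrix-decomposition form in which an elastic-net-constrained
sparse CCA with identity covariance assumptions reduces to sparse PLS.  The
L1 budgets c_u in [1, sqrt(p)] and c_v in [1, sqrt(q)] are the two
regularization parameters (one per view): c = 1 forces a single nonzero
weight, c = sqrt(d) makes the L1 constraint inactive on the unit sphere and
recovers plain PLS (the leading singular pair of X'Y).

Each alternating step is an L1-constrained unit-norm projection of the
current covariance direction, computed by bisection over the soft threshold.
Successive effects are obtained by projection deflation of both views.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

from ._utils import logger, safe_pearson

_BISECT_TOL = 1e-8
_BISECT_MAX_ITER = 200


class DegenerateInputError(ValueError):
    """Input is all-zero or otherwise carries no usable signal."""


@dataclass(frozen=True)
class SparsityPair:
    """L1 budgets (c_u, c_v), one per view; validated against view widths at
    fit time since the admissible interval [1, sqrt(d)] depends on d."""

    c_u: float
    c_v: float

    def __post_init__(self) -> None:
        if self.c_u < 1.0 or self.c_v < 1.0:
            raise ValueError("L1 budgets must be >= 1")

    def as_dict(self) -> dict:
        return {"c_u": float(self.c_u), "c_v": float(self.c_v)}


@dataclass
class EffectModel:
    """One fitted latent effect: a unit weight vector per view plus
    diagnostics.  ``train_correlation`` is the Pearson correlation of the
    training scores (Xu, Yv), made nonnegative by flipping v if needed."""

    u: np.ndarray
    v: np.ndarray
    hyperparams: Union[SparsityPair, "object"]
    train_correlation: float
    n_iterations: int
    converged: bool

    @property
    def support_u(self) -> np.ndarray:
        return np.flatnonzero(self.u)

    @property
    def support_v(self) -> np.ndarray:
        return np.flatnonzero(self.v)


def soft_threshold(a: np.ndarray, delta: float) -> np.ndarray:
    """Elementwise lasso shrinkage sign(a) * max(|a| - delta, 0)."""
    if delta < 0:
        raise ValueError(f"threshold must be nonnegative, got {delta}")
    a = np.asarray(a, dtype=float)
    return np.sign(a) * np.maximum(np.abs(a) - delta, 0.0)


def _unit_l1(a: np.ndarray, delta: float) -> tuple[np.ndarray, float]:
    s = soft_threshold(a, delta)
    norm = np.linalg.norm(s)
    if norm == 0.0:
        return s, np.inf
    w = s / norm
    return w, float(np.abs(w).sum())


def l1_constrained_unit(a: np.ndarray, c: float) -> np.ndarray:
    """Project direction ``a`` onto {w : ||w||_2 = 1, ||w||_1 <= c}.

    Returns S(a, delta) / ||S(a, delta)||_2 with the smallest soft threshold
    delta >= 0 achieving the L1 budget: bisection brackets the active set,
    then the threshold is solved in closed form (within a fixed active set
    the budget equation ||S||_1 = c ||S||_2 is quadratic in delta), so the
    alternating objective is monotone to machine precision.  Budgets at or
    above sqrt(d) are inactive; when the budget is unreachable (it can drop
    no lower than sqrt(m) with m the count of tied maximal magnitudes), the
    one-hot vector at the lowest-index maximum is returned.
    """
    a = np.asarray(a, dtype=float)
    d = a.size
    if not np.any(a):
        raise DegenerateInputError("cannot project an all-zero direction")
    if c < 1.0:
        raise ValueError(f"L1 budget must be >= 1, got {c}")

    w, l1 = _unit_l1(a, 0.0)
    if l1 <= c + 1e-12:
        return w

    abs_a = np.abs(a)
    # the achievable minimum of the L1 norm is sqrt(#ties at max |a_i|)
    top = abs_a.max()
    ties = abs_a >= top * (1.0 - 1e-12)
    if c < np.sqrt(ties.sum()) - 1e-12:
        j = int(np.argmax(ties))  # lowest index among tied maxima
        w = np.zeros(d)
        w[j] = np.sign(a[j]) if a[j] != 0 else 1.0
        return w

    lo, hi = 0.0, top
    for _ in range(_BISECT_MAX_ITER):
        mid = 0.5 * (lo + hi)
        _, l1_mid = _unit_l1(a, mid)
        if l1_mid <= c:
            hi = mid
        else:
            lo = mid
        if hi - lo < _BISECT_TOL:
            break

    # exact threshold within the bracketed active set A = {i: |a_i| > delta}:
    # with m = |A|, S1 = sum_A |a_i|, S2 = sum_A a_i^2, solve
    # (S1 - m d)^2 = c^2 (S2 - 2 S1 d + m d^2) for the root in (lo, hi]
    active = abs_a > hi
    m = int(active.sum())
    s1 = abs_a[active].sum()
    s2 = float(np.sum(abs_a[active] ** 2))
    aa = m * (m - c**2)
    bb = 2.0 * s1 * (c**2 - m)
    cc = s1**2 - c**2 * s2
    delta = hi
    if aa != 0.0:
        disc = bb**2 - 4.0 * aa * cc
        if disc >= 0.0:
            for root in ((-bb - np.sqrt(disc)) / (2 * aa), (-bb + np.sqrt(disc)) / (2 * aa)):
                if lo - 1e-12 <= root <= hi + 1e-12:
                    # consistency: the root must preserve the active set
                    if np.array_equal(abs_a > root, active) or np.isclose(root, hi):
                        delta = min(max(root, 0.0), hi)
                        break
    w, l1 = _unit_l1(a, delta)
    if not np.isfinite(l1) or l1 > c + 1e-9:
        w, l1 = _unit_l1(a, hi)
    if not np.isfinite(l1):  # hi collapsed onto the max; fall back to one-hot
        j = int(np.argmax(ties))
        w = np.zeros(d)
        w[j] = np.sign(a[j]) if a[j] != 0 else 1.0
    return w


def _spls_from_cross(
    m: np.ndarray,
    sparsity: SparsityPair,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray, int, bool]:
    """Alternating maximization given the cross-product matrix m = X'Y.

    Initialization is the leading right singular vector of m (deterministic;
    no random restarts), so repeated fits of the same data are identical.
    """
    if not np.any(m):
        raise DegenerateInputError("X'Y is exactly zero; no cross-view signal")
    p, q = m.shape
    _, _, vt = np.linalg.svd(m, full_matrices=False)
    v = vt[0]
    u = np.zeros(p)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        u_new = l1_constrained_unit(m @ v, sparsity.c_u)
        v_new = l1_constrained_unit(m.T @ u_new, sparsity.c_v)
        delta = max(np.linalg.norm(u_new - u), np.linalg.norm(v_new - v))
        u, v = u_new, v_new
        if delta < tol:
            converged = True
            break
    if not converged:
        logger.warning("SPLS did not converge in %d iterations", max_iter)
    return u, v, it, converged


def spls_fit(
    x: np.ndarray,
    y: np.ndarray,
    sparsity: SparsityPair,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> EffectModel:
    """Fit one sparse-PLS effect on centered matrices X (n x p), Y (n x q)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape[0] != y.shape[0]:
        raise ValueError("X and Y must have the same number of rows")
    if x.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    if tol <= 0:
        raise ValueError("tol must be positive")
    u, v, n_iter, converged = _spls_from_cross(x.T @ y, sparsity, tol, max_iter)
    r = safe_pearson(x @ u, y @ v)
    if r < 0:  # sign convention: training correlation is nonnegative
        v = -v
        r = -r
    return EffectModel(u, v, sparsity, r, n_iter, converged)


def compute_scores(x: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Per-sample projection X u of a view onto a weight vector."""
    x = np.asarray(x, dtype=float)
    u = np.asarray(u, dtype=float)
    if x.shape[1] != u.shape[0]:
        raise ValueError(f"cannot project {x.shape} matrix with length-{u.size} weights")
    return x @ u


def deflate(x: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Projection deflation X (I - u u'), removing an extracted effect so the
    next one is sought in the orthogonal complement; (X_defl) u = 0."""
    u = np.asarray(u, dtype=float)
    if abs(np.linalg.norm(u) - 1.0) > 1e-6:
        raise ValueError("deflation requires a unit-norm weight vector")
    x = np.asarray(x, dtype=float)
    return x - np.outer(x @ u, u)
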