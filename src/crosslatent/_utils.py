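"""Shared numerical helpers: seeding, correlations, ranking."""
from __future__ import annotations

import logging

import numpy as np

logger = logging.getLogger("crosslatent")


def spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Spawn ``n`` independent generators from a single master seed.

    All randomness in the package flows through this helper so that a run is
    fully determined by one integer.
    """
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(child) for child in ss.spawn(n)]


def safe_pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation that returns 0.0 (with a warning) for degenerate
    zero-variance inputs instead of NaN."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError(f"length mismatch: {a.size} vs {b.size}")
    ac = a - a.mean()
    bc = b - b.mean()
    denom = np.linalg.norm(ac) * np.linalg.norm(bc)
    if denom == 0.0 or not np.isfinite(denom):
        logger.warning("zero-variance score vector in correlation; returning 0")
        return 0.0
    return float(np.dot(ac, bc) / denom)


def rank_descending(values: np.ndarray) -> np.ndarray:
    """Rank values so the largest gets rank 1; ties share the average rank."""
    from scipy.stats import rankdata

    return rankdata(-np.asarray(values, dtype=float), method="average")
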