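"""Paired-view data with known sparse cross-modality latent structure.

The generator emulates the setting the framework targets: two
high-dimensional views (think voxelwise gray-matter volumes and item-level
questionnaire responses) measured on the same samples, sharing one or more
latent factors that each load on a small, disjoint subset of features per
view, plus shared confounds and independent noise:

    X = sum_k s_k z_k u_k' + gamma * F G_x + E_x
    Y = sum_k s_k z_k v_k' + gamma * F G_y + E_y

with z_k ~ N(0,1) latents, sparse unit loading vectors u_k, v_k, confound
values F ~ N(0,1) with random unit loading rows G, confound strength gamma,
and iid Gaussian noise.  Every draw is reproducible from the spec's seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ._utils import safe_pearson
from .dataview import DataView, PairedDataset
from .spls import EffectModel


class GeneratorSpecError(ValueError):
    pass


@dataclass
class GeneratorSpec:
    """Parameters of one synthetic paired dataset.

    ``support_fraction`` is the fraction of each view's features carrying a
    given effect; supports of distinct effects within a view are disjoint.
    ``effect_strengths`` are the signal standard deviations per factor and
    must be strictly decreasing so the extraction order is identifiable.
    """

    n: int = 200
    p: int = 50
    q: int = 50
    n_effects: int = 1
    support_fraction: float = 0.1
    effect_strengths: tuple[float, ...] = (3.0,)
    noise_sd: float = 1.0
    confound_strength: float = 0.0
    n_confounds: int = 0
    seed: int = 0
    latent_df: Optional[float] = None  # Student-t degrees of freedom; None = Gaussian
    decaying_magnitudes: bool = False

    def __post_init__(self) -> None:
        if self.n < 3 or self.p < 2 or self.q < 2:
            raise GeneratorSpecError("need n >= 3 and p, q >= 2")
        if self.n_effects < 0 or self.n_confounds < 0:
            raise GeneratorSpecError("counts must be nonnegative")
        if len(self.effect_strengths) < self.n_effects:
            raise GeneratorSpecError("one strength per effect required")
        strengths = self.effect_strengths[: self.n_effects]
        if any(s <= 0 for s in strengths):
            raise GeneratorSpecError("effect strengths must be positive")
        if any(a <= b for a, b in zip(strengths, strengths[1:])):
            raise GeneratorSpecError("effect strengths must be strictly decreasing")
        if self.noise_sd <= 0:
            raise GeneratorSpecError("noise_sd must be positive")
        if self.confound_strength < 0:
            raise GeneratorSpecError("confound_strength must be nonnegative")
        if not 0.0 < self.support_fraction <= 1.0:
            raise GeneratorSpecError("support_fraction must lie in (0, 1]")
        for d in (self.p, self.q):
            if self.n_effects * max(1, round(self.support_fraction * d)) > d:
                raise GeneratorSpecError(
                    "disjoint supports of this size do not fit in the view"
                )


@dataclass
class GroundTruth:
    """The planted structure: per-effect sparse unit loadings, the latent
    factor values, and the confound values."""

    true_u: list[np.ndarray] = field(default_factory=list)
    true_v: list[np.ndarray] = field(default_factory=list)
    true_latents: np.ndarray = field(default_factory=lambda: np.zeros((0, 0)))
    confound_values: np.ndarray = field(default_factory=lambda: np.zeros((0, 0)))


def _sparse_unit(
    rng: np.random.Generator, d: int, support: np.ndarray, decaying: bool
) -> np.ndarray:
    w = np.zeros(d)
    signs = rng.choice([-1.0, 1.0], size=support.size)
    mags = 0.5 ** np.arange(support.size) if decaying else np.ones(support.size)
    w[support] = signs * mags
    return w / np.linalg.norm(w)


def generate(spec: GeneratorSpec) -> tuple[PairedDataset, GroundTruth]:
    """Draw one paired dataset and its ground truth from the spec."""
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    n, p, q = spec.n, spec.p, spec.q
    k_u = max(1, round(spec.support_fraction * p))
    k_v = max(1, round(spec.support_fraction * q))

    if spec.latent_df is not None:
        z = rng.standard_t(spec.latent_df, size=(n, spec.n_effects))
        z /= np.sqrt(spec.latent_df / (spec.latent_df - 2.0))
    else:
        z = rng.standard_normal((n, spec.n_effects))

    perm_u = rng.permutation(p)
    perm_v = rng.permutation(q)
    true_u, true_v = [], []
    x = np.zeros((n, p))
    y = np.zeros((n, q))
    for k in range(spec.n_effects):
        u = _sparse_unit(rng, p, np.sort(perm_u[k * k_u : (k + 1) * k_u]), spec.decaying_magnitudes)
        v = _sparse_unit(rng, q, np.sort(perm_v[k * k_v : (k + 1) * k_v]), spec.decaying_magnitudes)
        s = spec.effect_strengths[k]
        x += s * np.outer(z[:, k], u)
        y += s * np.outer(z[:, k], v)
        true_u.append(u)
        true_v.append(v)

    confounds = np.zeros((n, spec.n_confounds))
    if spec.n_confounds > 0:
        confounds = rng.standard_normal((n, spec.n_confounds))
        if spec.confound_strength > 0:
            gx = rng.standard_normal((spec.n_confounds, p))
            gx /= np.linalg.norm(gx, axis=1, keepdims=True)
            gy = rng.standard_normal((spec.n_confounds, q))
            gy /= np.linalg.norm(gy, axis=1, keepdims=True)
            x += spec.confound_strength * confounds @ gx
            y += spec.confound_strength * confounds @ gy

    x += spec.noise_sd * rng.standard_normal((n, p))
    y += spec.noise_sd * rng.standard_normal((n, q))

    ids = [f"s{i + 1}" for i in range(n)]
    dataset = PairedDataset(
        DataView(x, [f"x{j + 1}" for j in range(p)], ids),
        DataView(y, [f"y{j + 1}" for j in range(q)], ids),
        (
            DataView(confounds, [f"c{j + 1}" for j in range(spec.n_confounds)], ids)
            if spec.n_confounds > 0
            else None
        ),
    )
    truth = GroundTruth(true_u, true_v, z, confounds)
    return dataset, truth


def _support_f1(estimated: np.ndarray, true_support: np.ndarray) -> float:
    est = set(np.flatnonzero(estimated).tolist())
    tru = set(true_support.tolist())
    if not est and not tru:
        return 1.0
    if not est or not tru:
        return 0.0
    tp = len(est & tru)
    precision = tp / len(est)
    recall = tp / len(tru)
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def recovery_metrics(
    estimated: EffectModel,
    truth: GroundTruth,
    effect_index: int,
    x: Optional[np.ndarray] = None,
    y: Optional[np.ndarray] = None,
) -> dict:
    """Sign-agnostic recovery report for one planted effect.

    Per view: support F1 of the estimated nonzeros against the true support,
    |cosine| between estimated and true loadings, and (when the data matrix
    is supplied) |correlation| between estimated scores and the true latent.
    """
    if not 0 <= effect_index < len(truth.true_u):
        raise IndexError(f"effect index {effect_index} out of range")
    tu, tv = truth.true_u[effect_index], truth.true_v[effect_index]
    if estimated.u.size != tu.size or estimated.v.size != tv.size:
        raise ValueError("estimated weight lengths do not match the ground truth")
    report = {
        "f1_u": _support_f1(estimated.u, np.flatnonzero(tu)),
        "f1_v": _support_f1(estimated.v, np.flatnonzero(tv)),
        "cosine_u": abs(float(estimated.u @ tu)),
        "cosine_v": abs(float(estimated.v @ tv)),
    }
    z = truth.true_latents[:, effect_index]
    if x is not None:
        report["latent_corr_u"] = abs(safe_pearson(x @ estimated.u, z))
    if y is not None:
        report["latent_corr_v"] = abs(safe_pearson(y @ estimated.v, z))
    return report
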