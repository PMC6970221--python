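"""Nested multiple-holdout resampling with joint stability/generalizability
hyperparameter selection and holdout permutation inference.

The data are repeatedly split into an optimization set (default 80%) and a
holdout set (default 20%).  Within each optimization set, hyperparameters
are chosen over further training/validation splits (default 50) by ranking
every grid cell on two criteria at once — mean validation out-of-sample
correlation (generalizability) and similarity of the fitted weights across
splits (stability: chance-corrected support overlap for sparse PLS,
absolute weight correlation for kernel CCA) — and taking the minimal rank
sum.  The winning cell is refit on the whole optimization set and evaluated
on the holdout set by a permutation test that re-pairs the rows of one
view.  The whole procedure repeats over the outer splits; an effect is
declared significant from the across-split p-values, deflated out of every
split, and the search continues until a non-significant effect or the cap.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from ._utils import logger, rank_descending, safe_pearson
from .config import ConfigError, RunConfig, default_kcca_grid, default_spls_grid
from .dataview import PairedDataset
from .kcca import KccaParams, KernelBasis, kcca_fit, linear_kernel, recover_primal_weights
from .preprocess import (
    apply_centering,
    apply_confound_model,
    fit_centering,
    fit_confound_model,
)
from .spls import (
    DegenerateInputError,
    EffectModel,
    SparsityPair,
    _spls_from_cross,
    deflate,
)

__all__ = [
    "SplitScheme",
    "GridCell",
    "SplitEffect",
    "EffectResult",
    "make_splits",
    "out_of_sample_correlation",
    "corrected_overlap",
    "weight_correlation_stability",
    "grid_search",
    "select_hyperparams",
    "holdout_permutation_test",
    "decide_significance",
    "choose_best_split",
    "run_framework",
]


# ---------------------------------------------------------------------------
# resampling plan


@dataclass
class SplitScheme:
    """Fully seeded nested resampling plan.

    ``outer_splits[j]`` is an (optimization_indices, holdout_indices) partition
    of range(n); ``inner_splits[j]`` is the list of (training, validation)
    partitions of ``outer_splits[j][0]``.
    """

    outer_splits: list[tuple[np.ndarray, np.ndarray]]
    inner_splits: list[list[tuple[np.ndarray, np.ndarray]]]
    seed: int


def make_splits(n: int, config: RunConfig) -> SplitScheme:
    """Draw the uniform-random nested splits for ``n`` samples."""
    if n < 10:
        raise ConfigError(f"need at least 10 samples to split, got {n}")
    n_hold = int(round(config.holdout_fraction * n))
    if n_hold < 2 or n - n_hold < 4:
        raise ConfigError(f"holdout size {n_hold} of {n} leaves too few samples")
    n_opt = n - n_hold
    n_val = int(round(config.validation_fraction * n_opt))
    if n_val < 2 or n_opt - n_val < 3:
        raise ConfigError(f"validation size {n_val} of {n_opt} leaves too few samples")

    ss = np.random.SeedSequence(config.seed).spawn(1)[0]
    rng = np.random.default_rng(ss)
    outer, inner = [], []
    for _ in range(config.n_outer_splits):
        perm = rng.permutation(n)
        hold = np.sort(perm[:n_hold])
        opt = np.sort(perm[n_hold:])
        outer.append((opt, hold))
        pairs = []
        for _ in range(config.n_inner_splits):
            iperm = rng.permutation(n_opt)
            val = np.sort(opt[iperm[:n_val]])
            train = np.sort(opt[iperm[n_val:]])
            pairs.append((train, val))
        inner.append(pairs)
    return SplitScheme(outer, inner, config.seed)


# ---------------------------------------------------------------------------
# evaluation metrics


def out_of_sample_correlation(
    model: EffectModel, x_new: np.ndarray, y_new: np.ndarray
) -> float:
    """Signed Pearson correlation of held-out scores (X u, Y v).

    The model's sign convention (training correlation >= 0) carries over, so
    a negative value means the effect reversed out of sample.
    """
    return safe_pearson(x_new @ model.u, y_new @ model.v)


def corrected_overlap(supports: Sequence[Sequence[int]], d: int) -> float:
    """Chance-corrected pairwise agreement of sparse supports.

    For each unordered pair of support sets, (|A&B| - |A||B|/d) /
    (min(|A|,|B|) - |A||B|/d); pairs whose denominator is nonpositive (empty
    or full supports) contribute 0.  Equals 1 iff all nonempty proper
    supports are identical; random supports average near 0.
    """
    if len(supports) < 2:
        raise ValueError("need at least 2 support sets")
    if d < 1:
        raise ValueError("d must be positive")
    sets = [frozenset(int(i) for i in s) for s in supports]
    total = 0.0
    n_pairs = 0
    for a, b in itertools.combinations(sets, 2):
        n_pairs += 1
        expected = len(a) * len(b) / d
        denom = min(len(a), len(b)) - expected
        if denom > 0:
            total += (len(a & b) - expected) / denom
    return total / n_pairs


def weight_correlation_stability(weights: Sequence[np.ndarray]) -> float:
    """Mean absolute Pearson correlation over all unordered weight pairs."""
    if len(weights) < 2:
        raise ValueError("need at least 2 weight vectors")
    ws = [np.asarray(w, dtype=float) for w in weights]
    if len({w.size for w in ws}) != 1:
        raise ValueError("weight vectors must share a length")
    vals = [abs(safe_pearson(a, b)) for a, b in itertools.combinations(ws, 2)]
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# model backends (one per family, sharing the framework loop)


class SplsBackend:
    """Sparse PLS: hyperparameters are per-view L1 budgets; stability is the
    corrected support overlap averaged over the two views."""

    kind = "spls"

    def __init__(self, tol: float = 1e-6, max_iter: int = 500):
        self.tol = tol
        self.max_iter = max_iter

    def grid_cells(self, config: RunConfig, p: int, q: int) -> list[SparsityPair]:
        gx = config.grid_x if config.grid_x is not None else default_spls_grid(p)
        gy = config.grid_y if config.grid_y is not None else default_spls_grid(q)
        if max(gx) > np.sqrt(p) + 1e-9 or max(gy) > np.sqrt(q) + 1e-9:
            raise ConfigError("SPLS grid exceeds sqrt(d) for a view")
        return [SparsityPair(cu, cv) for cu in gx for cv in gy]

    def prepare(self, x: np.ndarray, y: np.ndarray):
        return x.T @ y

    def fit_prepared(self, ctx, x, y, hyperparams: SparsityPair) -> EffectModel:
        u, v, n_iter, converged = _spls_from_cross(
            ctx, hyperparams, self.tol, self.max_iter
        )
        r = safe_pearson(x @ u, y @ v)
        if r < 0:
            v, r = -v, -r
        return EffectModel(u, v, hyperparams, r, n_iter, converged)

    def fit(self, x, y, hyperparams) -> EffectModel:
        return self.fit_prepared(self.prepare(x, y), x, y, hyperparams)

    def stability(self, models: Sequence[EffectModel], p: int, q: int) -> float:
        s_u = corrected_overlap([m.support_u for m in models], p)
        s_v = corrected_overlap([m.support_v for m in models], q)
        return 0.5 * (s_u + s_v)

    @staticmethod
    def regularization_strength(hp: SparsityPair) -> float:
        # smaller L1 budget = more regularized
        return -(hp.c_u + hp.c_v)


class KccaBackend:
    """Regularized kernel CCA: hyperparameters are per-view kappa values;
    stability is the mean absolute correlation of the primal weights."""

    kind = "kcca"

    def grid_cells(self, config: RunConfig, p: int, q: int) -> list[KccaParams]:
        gx = config.grid_x if config.grid_x is not None else default_kcca_grid()
        gy = config.grid_y if config.grid_y is not None else default_kcca_grid()
        return [KccaParams(kx, ky) for kx in gx for ky in gy]

    def prepare(self, x: np.ndarray, y: np.ndarray):
        return (
            KernelBasis.from_kernel(linear_kernel(x)),
            KernelBasis.from_kernel(linear_kernel(y)),
        )

    def fit_prepared(self, ctx, x, y, hyperparams: KccaParams) -> EffectModel:
        basis_x, basis_y = ctx
        dual = kcca_fit(None, None, hyperparams, basis_x=basis_x, basis_y=basis_y)
        u = recover_primal_weights(x, dual.alpha)
        v = recover_primal_weights(y, dual.beta)
        r = safe_pearson(x @ u, y @ v)
        if r < 0:
            v, r = -v, -r
        return EffectModel(u, v, hyperparams, r, 1, True)

    def fit(self, x, y, hyperparams) -> EffectModel:
        return self.fit_prepared(self.prepare(x, y), x, y, hyperparams)

    def stability(self, models: Sequence[EffectModel], p: int, q: int) -> float:
        s_u = weight_correlation_stability([m.u for m in models])
        s_v = weight_correlation_stability([m.v for m in models])
        return 0.5 * (s_u + s_v)

    @staticmethod
    def regularization_strength(hp: KccaParams) -> float:
        # larger kappa = more regularized
        return hp.kappa_x + hp.kappa_y


def get_backend(config: RunConfig):
    if config.model == "spls":
        return SplsBackend(config.spls_tol, config.spls_max_iter)
    return KccaBackend()


# ---------------------------------------------------------------------------
# grid search and selection


@dataclass
class GridCell:
    """One hyperparameter combination with its inner-split statistics."""

    hyperparams: Union[SparsityPair, KccaParams]
    mean_validation_correlation: float
    stability: float
    n_degenerate: int = 0
    valid: bool = True
    rank_sum: float = float("nan")


def grid_search(
    opt_x: np.ndarray,
    opt_y: np.ndarray,
    inner_splits: Sequence[tuple[np.ndarray, np.ndarray]],
    cells: Sequence[Union[SparsityPair, KccaParams]],
    backend,
) -> list[GridCell]:
    """Evaluate every grid cell over the inner training/validation splits.

    ``opt_x``/``opt_y`` are the (already residualized and centered)
    optimization-set matrices; ``inner_splits`` contains positional
    (training, validation) index pairs into their rows.  Each inner training
    set is re-centered before fitting (validation rows get the training
    means), keeping the validation correlation leakage-free.
    """
    if len(cells) == 0:
        raise ValueError("empty hyperparameter grid")
    per_cell_corrs: list[list[float]] = [[] for _ in cells]
    per_cell_models: list[list[EffectModel]] = [[] for _ in cells]
    n_degen = [0] * len(cells)
    for train, val in inner_splits:
        xt, xv = opt_x[train], opt_x[val]
        yt, yv = opt_y[train], opt_y[val]
        mx, my = xt.mean(axis=0), yt.mean(axis=0)
        xt, xv = xt - mx, xv - mx
        yt, yv = yt - my, yv - my
        try:
            ctx = backend.prepare(xt, yt)
        except DegenerateInputError:
            for i in range(len(cells)):
                n_degen[i] += 1
            continue
        for i, hp in enumerate(cells):
            try:
                model = backend.fit_prepared(ctx, xt, yt, hp)
            except DegenerateInputError:
                n_degen[i] += 1
                continue
            per_cell_corrs[i].append(safe_pearson(xv @ model.u, yv @ model.v))
            per_cell_models[i].append(model)

    n_splits = len(inner_splits)
    p, q = opt_x.shape[1], opt_y.shape[1]
    out = []
    for i, hp in enumerate(cells):
        corrs, models = per_cell_corrs[i], per_cell_models[i]
        valid = len(models) >= 2 and n_degen[i] <= 0.5 * n_splits
        if n_degen[i]:
            logger.warning(
                "grid cell %s: %d/%d degenerate fits excluded", hp, n_degen[i], n_splits
            )
        if valid:
            cell = GridCell(hp, float(np.mean(corrs)), backend.stability(models, p, q), n_degen[i], True)
        else:
            cell = GridCell(hp, float("nan"), float("nan"), n_degen[i], False)
        out.append(cell)
    return out


class FrameworkError(RuntimeError):
    """A framework stage failed irrecoverably."""


def select_hyperparams(cells: Sequence[GridCell], backend=None) -> GridCell:
    """Joint stability/generalizability selection by minimal rank sum.

    Valid cells are ranked (descending) on mean validation correlation and on
    stability; the cell with the smallest rank sum wins.  Ties go to the
    higher validation correlation, then to the more regularized cell.
    """
    valid = [c for c in cells if c.valid]
    if not valid:
        raise FrameworkError("no valid grid cell to select from")
    corr_ranks = rank_descending(np.array([c.mean_validation_correlation for c in valid]))
    stab_ranks = rank_descending(np.array([c.stability for c in valid]))
    for cell, rc, rs in zip(valid, corr_ranks, stab_ranks):
        cell.rank_sum = float(rc + rs)

    def reg(cell: GridCell) -> float:
        if backend is None:
            return 0.0
        return backend.regularization_strength(cell.hyperparams)

    return min(
        valid, key=lambda c: (c.rank_sum, -c.mean_validation_correlation, -reg(c))
    )


# ---------------------------------------------------------------------------
# permutation inference


def holdout_permutation_test(
    model: EffectModel,
    holdout_x: np.ndarray,
    holdout_y: np.ndarray,
    n_permutations: int,
    seed: Union[int, np.random.Generator],
) -> tuple[float, float]:
    """One-sided permutation test of the holdout correlation.

    The null distribution re-pairs samples by permuting the holdout rows of
    the y view; p = (1 + #{r_perm >= r_obs}) / (n_permutations + 1).  The
    one-sided form is coherent because the training sign convention fixes the
    expected correlation to be positive.
    """
    if holdout_x.shape[0] < 5:
        raise ValueError(f"holdout of {holdout_x.shape[0]} samples is too small to test")
    if n_permutations < 19:
        raise ValueError("need at least 19 permutations to resolve p < 0.05")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x_scores = holdout_x @ model.u
    y_scores = holdout_y @ model.v
    r_obs = safe_pearson(x_scores, y_scores)

    xc = x_scores - x_scores.mean()
    yc = y_scores - y_scores.mean()
    denom = np.linalg.norm(xc) * np.linalg.norm(yc)  # invariant to permuting yc
    if denom == 0.0:
        logger.warning("degenerate holdout scores; permutation test returns p=1")
        return r_obs, 1.0
    n = x_scores.size
    idx = np.argsort(rng.random((n_permutations, n)), axis=1)
    r_perm = (yc[idx] @ xc) / denom
    exceed = int(np.sum(r_perm >= r_obs))
    p = (1 + exceed) / (n_permutations + 1)
    return r_obs, p


def decide_significance(
    p_values: Sequence[float], alpha: float, rule: str = "bonferroni_min"
) -> tuple[bool, int]:
    """Across-split significance verdict.

    Default rule: significant iff min(p) <= alpha / n_splits (Bonferroni over
    the outer splits; the non-strict comparison is the valid rejection rule
    for discrete permutation p-values, whose smallest achievable value
    1/(n_permutations+1) can coincide with the threshold).  Also returns the
    count of splits with p < alpha.
    """
    p = np.asarray(p_values, dtype=float)
    n_below = int(np.sum(p < alpha))
    if rule == "bonferroni_min":
        return bool(p.min() <= alpha / p.size), n_below
    if rule == "majority":
        return bool(n_below > 0.5 * p.size), n_below
    raise ValueError(f"unknown significance rule {rule!r}")


def choose_best_split(
    holdout_correlations: Sequence[float], stabilities: Sequence[float]
) -> int:
    """Rank splits on holdout correlation and stability; minimal rank sum wins,
    with ties going to the higher holdout correlation."""
    if len(holdout_correlations) == 0:
        raise ValueError("no splits to choose from")
    rc = rank_descending(np.asarray(holdout_correlations, dtype=float))
    rs = rank_descending(np.asarray(stabilities, dtype=float))
    sums = rc + rs
    order = sorted(
        range(len(sums)), key=lambda j: (sums[j], -holdout_correlations[j], j)
    )
    return order[0]


# ---------------------------------------------------------------------------
# the full pipeline


@dataclass
class SplitEffect:
    """One effect's outcome within one outer split."""

    split_index: int
    model: EffectModel
    holdout_correlation: float
    p_value: float
    chosen_hyperparams: Union[SparsityPair, KccaParams]
    stability_at_chosen: float
    grid: list[GridCell] = field(repr=False, default_factory=list)


@dataclass
class EffectResult:
    """One latent effect across all outer splits, with the across-split
    significance verdict and the best-split designation."""

    effect_index: int  # 1-based
    per_split: list[SplitEffect]
    significant: bool
    n_splits_below_alpha: int
    best_split_index: int

    @property
    def p_values(self) -> list[float]:
        return [s.p_value for s in self.per_split]

    @property
    def holdout_correlations(self) -> list[float]:
        return [s.holdout_correlation for s in self.per_split]


def _preprocess_outer(
    data: PairedDataset,
    opt_idx: np.ndarray,
    hold_idx: np.ndarray,
    config: RunConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Residualize confounds and center/scale, fitting on optimization rows
    only; returns (x_opt, y_opt, x_hold, y_hold) matrices."""
    views = {}
    for tag, view in (("x", data.x), ("y", data.y)):
        v_opt = view.subset_rows(opt_idx)
        v_hold = view.subset_rows(hold_idx)
        if data.confounds is not None and not config.global_confound_removal:
            c_opt = data.confounds.subset_rows(opt_idx)
            c_hold = data.confounds.subset_rows(hold_idx)
            cm = fit_confound_model(v_opt, c_opt, view_tag=tag)
            v_opt = apply_confound_model(v_opt, c_opt, cm)
            v_hold = apply_confound_model(v_hold, c_hold, cm)
        center = fit_centering(v_opt, scale=config.scale_features)
        views[tag] = (
            apply_centering(v_opt, center).values,
            apply_centering(v_hold, center).values,
        )
    return views["x"][0], views["y"][0], views["x"][1], views["y"][1]


def run_framework(data: PairedDataset, config: RunConfig) -> list[EffectResult]:
    """Run the full multiple-holdout analysis and return one
    :class:`EffectResult` per extracted effect (the last one is the first
    non-significant effect unless the cap was reached)."""
    n = data.n_samples
    if n < 25:
        logger.warning("only %d samples; results will be unstable", n)
    backend = get_backend(config)
    scheme = make_splits(n, config)

    if data.confounds is not None and config.global_confound_removal:
        # simpler, leaky variant: residualize once on all rows
        views = []
        for tag, view in (("x", data.x), ("y", data.y)):
            cm = fit_confound_model(view, data.confounds, view_tag=tag)
            views.append(apply_confound_model(view, data.confounds, cm))
        data = PairedDataset(views[0], views[1], None)

    # per-split preprocessed matrices; deflation updates these in place
    states = []
    for opt_idx, hold_idx in scheme.outer_splits:
        states.append(_preprocess_outer(data, opt_idx, hold_idx, config))

    cells_template = backend.grid_cells(config, data.x.n_features, data.y.n_features)

    # independent permutation streams per (effect, split), spawned from the
    # master seed so they cannot depend on data content
    perm_ss = np.random.SeedSequence(config.seed).spawn(2)[1]
    perm_children = perm_ss.spawn(config.max_effects * config.n_outer_splits)

    min_ok = max(2, int(np.ceil(0.8 * config.n_outer_splits)))
    results: list[EffectResult] = []
    for k in range(1, config.max_effects + 1):
        per_split: list[SplitEffect] = []
        for j in range(config.n_outer_splits):
            x_opt, y_opt, x_hold, y_hold = states[j]
            # positional inner indices within the optimization set
            opt_idx = scheme.outer_splits[j][0]
            pos = {s: i for i, s in enumerate(opt_idx)}
            inner_pos = [
                (
                    np.array([pos[s] for s in train], dtype=int),
                    np.array([pos[s] for s in val], dtype=int),
                )
                for train, val in scheme.inner_splits[j]
            ]
            try:
                grid = grid_search(x_opt, y_opt, inner_pos, cells_template, backend)
                chosen = select_hyperparams(grid, backend)
                model = backend.fit(x_opt, y_opt, chosen.hyperparams)
                rng = np.random.default_rng(
                    perm_children[(k - 1) * config.n_outer_splits + j]
                )
                r_obs, p = holdout_permutation_test(
                    model, x_hold, y_hold, config.n_permutations, rng
                )
            except (DegenerateInputError, FrameworkError) as exc:
                logger.warning("effect %d split %d failed: %s", k, j, exc)
                continue
            per_split.append(
                SplitEffect(j, model, r_obs, p, chosen.hyperparams, chosen.stability, grid)
            )
        if len(per_split) < min(min_ok, config.n_outer_splits):
            raise FrameworkError(
                f"effect {k}: only {len(per_split)}/{config.n_outer_splits} splits succeeded"
            )
        significant, n_below = decide_significance(
            [s.p_value for s in per_split], config.alpha, config.significance_rule
        )
        best = choose_best_split(
            [s.holdout_correlation for s in per_split],
            [s.stability_at_chosen for s in per_split],
        )
        results.append(EffectResult(k, per_split, significant, n_below, best))
        if not significant or k == config.max_effects:
            break
        # deflate every split with its own optimization-set weights; holdout
        # rows are deflated with the same (training-derived) weights
        by_split = {s.split_index: s for s in per_split}
        new_states = []
        for j in range(config.n_outer_splits):
            x_opt, y_opt, x_hold, y_hold = states[j]
            if j in by_split:
                m = by_split[j].model
                x_opt = deflate(x_opt, m.u)
                x_hold = deflate(x_hold, m.u)
                y_opt = deflate(y_opt, m.v)
                y_hold = deflate(y_hold, m.v)
            new_states.append((x_opt, y_opt, x_hold, y_hold))
        states = new_states
    return results
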