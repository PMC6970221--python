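"""Run configuration: the knobs of the multiple-holdout framework.

Defaults mirror the resampling scheme the framework was designed around:
10 outer optimization/holdout splits at 80/20, 50 inner training/validation
splits per optimization set, permutation inference on each holdout set.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional


class ConfigError(ValueError):
    """Invalid run configuration."""


@dataclass
class RunConfig:
    """Configuration for :func:`crosslatent.framework.run_framework`.

    Parameters
    ----------
    model:
        ``"spls"`` (sparse partial least squares) or ``"kcca"`` (regularized
        kernel CCA with linear kernel).
    n_outer_splits:
        Number of outer optimization/holdout splits (default 10).
    holdout_fraction:
        Fraction of samples held out per outer split (default 0.2).
    n_inner_splits:
        Number of inner training/validation splits per optimization set
        (default 50).
    validation_fraction:
        Fraction of each optimization set used for validation (default 0.2,
        mirroring the outer 80/20 split).
    grid_x, grid_y:
        Per-view hyperparameter grids.  For SPLS these are L1 budgets
        ``c in [1, sqrt(d)]``; ``None`` means 10 logarithmically spaced values
        spanning that interval.  For KCCA they are interpolation parameters
        ``kappa in [0, 1]``; ``None`` means ``0, 0.1, ..., 1``.
    n_permutations:
        Permutations per holdout test (default 1000).
    alpha:
        Significance level (default 0.05).
    max_effects:
        Cap on the number of successively deflated effects (default 5).
    seed:
        Master seed; every random draw in a run descends from it.
    scale_features:
        Whether to scale columns to unit training standard deviation in
        addition to mean-centering (default off; centering is always on).
    global_confound_removal:
        If true, regress confounds out of the full dataset once, before any
        splitting (simpler but leaks holdout information into the confound
        fit); default is the leakage-free nested variant.
    significance_rule:
        ``"bonferroni_min"`` (default: min p across outer splits compared to
        alpha / n_outer_splits) or ``"majority"`` (more than half the splits
        with p < alpha).
    """

    model: str = "spls"
    n_outer_splits: int = 10
    holdout_fraction: float = 0.2
    n_inner_splits: int = 50
    validation_fraction: float = 0.2
    grid_x: Optional[list[float]] = None
    grid_y: Optional[list[float]] = None
    n_permutations: int = 1000
    alpha: float = 0.05
    max_effects: int = 5
    seed: int = 0
    scale_features: bool = False
    global_confound_removal: bool = False
    significance_rule: str = "bonferroni_min"
    spls_tol: float = 1e-6
    spls_max_iter: int = 500

    def __post_init__(self) -> None:
        if self.model not in ("spls", "kcca"):
            raise ConfigError(f"unknown model {self.model!r}; use 'spls' or 'kcca'")
        for name in ("n_outer_splits", "n_inner_splits", "n_permutations", "max_effects"):
            if int(getattr(self, name)) < 1:
                raise ConfigError(f"{name} must be a positive integer")
        for name in ("holdout_fraction", "validation_fraction", "alpha"):
            v = float(getattr(self, name))
            if not 0.0 < v < 1.0:
                raise ConfigError(f"{name} must lie strictly in (0, 1), got {v}")
        if self.significance_rule not in ("bonferroni_min", "majority"):
            raise ConfigError(f"unknown significance_rule {self.significance_rule!r}")
        for grid in (self.grid_x, self.grid_y):
            if grid is not None:
                if len(grid) == 0:
                    raise ConfigError("hyperparameter grid must be nonempty")
                if self.model == "kcca" and not all(0.0 <= g <= 1.0 for g in grid):
                    raise ConfigError("kcca grid values must lie in [0, 1]")
                if self.model == "spls" and not all(g >= 1.0 for g in grid):
                    raise ConfigError("spls grid values must be >= 1")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        try:
            payload = json.loads(text)
        except json.JSONDecodeError as exc:
            raise ConfigError(f"config is not valid JSON: {exc}") from exc
        known = {f for f in cls.__dataclass_fields__}  # noqa: C416
        unknown = set(payload) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        return cls(**payload)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_json(fh.read())


def default_spls_grid(d: int, n_points: int = 10) -> list[float]:
    """Logarithmically spaced L1 budgets spanning [1, sqrt(d)]."""
    import numpy as np

    return list(np.logspace(0.0, 0.5 * np.log10(d), n_points))


def default_kcca_grid() -> list[float]:
    return [round(0.1 * k, 1) for k in range(11)]
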