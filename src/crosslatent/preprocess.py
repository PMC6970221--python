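"""Out-of-sample-safe conditioning: confound regression and column centering.

Both transforms are *fitted* on training rows only and then *applied* to any
rows (training, validation, or holdout), so that no statistic of held-out
data ever enters a fit.  Confounds (e.g. total intracranial volume, scanner
site indicators) are removed by ordinary least squares per feature column,
including an intercept; centering/scaling uses training means and standard
deviations.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._utils import logger
from .dataview import DataContractError, DataView


@dataclass
class ConfoundModel:
    """Per-feature OLS coefficients of a view on [1, confounds].

    ``coefficients`` has shape (c+1, d): row 0 is the intercept, rows 1..c the
    confound slopes, one column per feature of the tagged view.
    """

    coefficients: np.ndarray
    feature_names: list[str]
    confound_names: list[str]
    view_tag: str = "x"

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if not np.all(np.isfinite(self.coefficients)):
            raise DataContractError("non-finite confound coefficients")
        if self.coefficients.shape != (len(self.confound_names) + 1, len(self.feature_names)):
            raise DataContractError("confound coefficient shape mismatch")


@dataclass
class CenteringModel:
    """Training-set column means and (optionally) scales of a view."""

    means: np.ndarray
    scales: np.ndarray
    feature_names: list[str]

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.scales = np.asarray(self.scales, dtype=float)
        if np.any(self.scales <= 0):
            raise DataContractError("scales must be strictly positive")


def _design(confounds: DataView) -> np.ndarray:
    n = confounds.n_samples
    return np.hstack([np.ones((n, 1)), confounds.values])


def fit_confound_model(
    train_view: DataView, train_confounds: DataView, view_tag: str = "x"
) -> ConfoundModel:
    """OLS fit of every feature column on [1, confounds] over training rows.

    Rank-deficient confound matrices are handled by the minimum-norm
    least-squares solution.
    """
    if train_view.sample_ids != train_confounds.sample_ids:
        raise DataContractError("view and confound rows are not aligned")
    n, c = train_confounds.values.shape
    if n <= c + 1:
        raise DataContractError(
            f"need more than {c + 1} training samples to fit {c} confounds, got {n}"
        )
    design = _design(train_confounds)
    coef, *_ = np.linalg.lstsq(design, train_view.values, rcond=None)
    return ConfoundModel(
        coef, list(train_view.feature_names), list(train_confounds.feature_names), view_tag
    )


def apply_confound_model(
    view: DataView, confounds: DataView, model: ConfoundModel
) -> DataView:
    """Residualize ``view`` against the fitted confound regression."""
    if view.feature_names != model.feature_names:
        raise DataContractError("view features do not match the fitted confound model")
    if confounds.feature_names != model.confound_names:
        raise DataContractError("confound columns do not match the fitted model")
    residuals = view.values - _design(confounds) @ model.coefficients
    return view.with_values(residuals)


def fit_centering(train_view: DataView, scale: bool = False) -> CenteringModel:
    """Column means (and, if ``scale``, standard deviations) of training rows.

    Constant training columns get scale 1 with a warning rather than dividing
    by zero.
    """
    means = train_view.values.mean(axis=0)
    if scale:
        scales = train_view.values.std(axis=0, ddof=0)
        zero = scales <= 0
        if np.any(zero):
            logger.warning(
                "%d constant training column(s); scale forced to 1", int(zero.sum())
            )
            scales = np.where(zero, 1.0, scales)
    else:
        scales = np.ones_like(means)
    return CenteringModel(means, scales, list(train_view.feature_names))


def apply_centering(view: DataView, model: CenteringModel) -> DataView:
    if view.feature_names != model.feature_names:
        raise DataContractError("view features do not match the fitted centering model")
    return view.with_values((view.values - model.means) / model.scales)
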