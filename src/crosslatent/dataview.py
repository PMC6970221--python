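"""Core data containers: a labelled numeric view and a paired two-view dataset.

A *view* is one modality measured on a common set of samples (e.g. voxelwise
gray-matter volumes, or item-level questionnaire responses).  The framework
relates two such views through sparse or regularized latent-variable models,
so the containers enforce the alignment and finiteness assumptions those
models rely on.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np


class DataContractError(ValueError):
    """A container invariant or operation precondition was violated."""


@dataclass
class DataView:
    """An (n samples x d features) numeric matrix with unique row/column labels.

    Invariants (checked at construction):

    * all entries finite (models assume complete matrices; no imputation),
    * ``feature_names`` and ``sample_ids`` unique,
    * n >= 3 and d >= 1.
    """

    values: np.ndarray
    feature_names: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataContractError("values must be a 2-D matrix")
        n, d = self.values.shape
        self.feature_names = [str(f) for f in self.feature_names]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(self.feature_names) != d:
            raise DataContractError(
                f"{len(self.feature_names)} feature names for {d} columns"
            )
        if len(self.sample_ids) != n:
            raise DataContractError(
                f"{len(self.sample_ids)} sample ids for {n} rows"
            )
        if len(set(self.feature_names)) != d:
            raise DataContractError("duplicate feature names")
        if len(set(self.sample_ids)) != n:
            raise DataContractError("duplicate sample ids")
        if n < 3:
            raise DataContractError(f"need at least 3 samples, got {n}")
        if d < 1:
            raise DataContractError("need at least 1 feature")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise DataContractError(
                "non-finite entry at row "
                f"{self.sample_ids[bad[0]]!r}, column {self.feature_names[bad[1]]!r}"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset_rows(self, indices: Sequence[int]) -> "DataView":
        idx = np.asarray(indices, dtype=int)
        return DataView(
            self.values[idx],
            list(self.feature_names),
            [self.sample_ids[i] for i in idx],
        )

    def with_values(self, values: np.ndarray) -> "DataView":
        """Same labels, new matrix (e.g. after residualization or centering)."""
        return DataView(values, list(self.feature_names), list(self.sample_ids))


@dataclass
class PairedDataset:
    """Two row-aligned views X (n x p) and Y (n x q), plus optional confounds.

    The rows of all members refer to the same samples in the same order.
    """

    x: DataView
    y: DataView
    confounds: Optional[DataView] = field(default=None)

    def __post_init__(self) -> None:
        if self.x.sample_ids != self.y.sample_ids:
            raise DataContractError("x and y sample ids differ or are reordered")
        if self.confounds is not None and self.confounds.sample_ids != self.x.sample_ids:
            raise DataContractError("confound sample ids differ from x/y")
        if self.x.n_features < 2 or self.y.n_features < 2:
            raise DataContractError("each view needs at least 2 features")

    @property
    def n_samples(self) -> int:
        return self.x.n_samples

    def subset_rows(self, indices: Sequence[int]) -> "PairedDataset":
        return PairedDataset(
            self.x.subset_rows(indices),
            self.y.subset_rows(indices),
            None if self.confounds is None else self.confounds.subset_rows(indices),
        )
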