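"""Reading and writing matrices, configs, and result artifacts.

Matrix files are delimited text with a header row of feature names and a
leading sample-ID column.  Views are aligned by sample ID (intersection, in
the order of the x file); missing or non-numeric entries are rejected rather
than imputed, since the models assume complete matrices.
"""
from __future__ import annotations

import json
import os
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from ._utils import logger
from .dataview import DataContractError, DataView, PairedDataset
from .framework import EffectResult


class ParseError(ValueError):
    """A matrix file could not be parsed into a numeric view."""


def _detect_delimiter(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_view(path: Union[str, Path], delimiter: Optional[str] = None) -> DataView:
    """Read one view from a CSV/TSV file (header = feature names, first
    column = sample ID)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = delimiter if delimiter is not None else _detect_delimiter(path)
    frame = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    if frame.index.has_duplicates:
        dupes = frame.index[frame.index.duplicated()].unique().tolist()
        raise ParseError(f"{path.name}: duplicate sample IDs {dupes[:5]}")
    values = np.empty(frame.shape, dtype=float)
    for j, col in enumerate(frame.columns):
        try:
            # numpy's str->float conversion is correctly rounded, preserving
            # the writer's full precision on round trips
            values[:, j] = frame[col].to_numpy(dtype=float)
        except (ValueError, TypeError):
            bad = frame[col][pd.to_numeric(frame[col], errors="coerce").isna()]
            row = bad.index[0] if len(bad) else "?"
            raise ParseError(
                f"{path.name}: non-numeric value at row {row!r}, column {col!r}"
            ) from None
    try:
        return DataView(values, list(frame.columns), list(frame.index.astype(str)))
    except DataContractError as exc:
        raise ParseError(f"{path.name}: {exc}") from exc


def write_view(view: DataView, path: Union[str, Path], delimiter: str = ",") -> None:
    frame = pd.DataFrame(view.values, index=view.sample_ids, columns=view.feature_names)
    frame.index.name = "sample_id"
    frame.to_csv(path, sep=delimiter, float_format="%.17g")


def load_paired_dataset(
    x_path: Union[str, Path],
    y_path: Union[str, Path],
    confound_path: Optional[Union[str, Path]] = None,
    delimiter: Optional[str] = None,
) -> PairedDataset:
    """Load two (or three) matrix files and align rows by sample ID.

    The intersection of IDs is taken, ordered as in the x file; dropped
    sample counts are logged.  Fewer than 3 shared samples is an error.
    """
    x = read_view(x_path, delimiter)
    y = read_view(y_path, delimiter)
    conf = read_view(confound_path, delimiter) if confound_path is not None else None

    shared = set(x.sample_ids) & set(y.sample_ids)
    if conf is not None:
        shared &= set(conf.sample_ids)
    order = [s for s in x.sample_ids if s in shared]
    if len(order) < 3:
        raise DataContractError(
            f"only {len(order)} shared sample IDs across files; need at least 3"
        )
    for name, view in (("x", x), ("y", y)) + ((("confounds", conf),) if conf else ()):
        dropped = view.n_samples - len(order)
        if dropped:
            logger.info("%s: dropped %d samples not shared across files", name, dropped)

    def take(view: DataView) -> DataView:
        pos = {s: i for i, s in enumerate(view.sample_ids)}
        return view.subset_rows([pos[s] for s in order])

    return PairedDataset(take(x), take(y), take(conf) if conf is not None else None)


# ---------------------------------------------------------------------------
# result artifacts


def _hyperparams_dict(hp) -> dict:
    return hp.as_dict()


def write_effect_report(
    results: list[EffectResult],
    out_dir: Union[str, Path],
    data: Optional[PairedDataset] = None,
) -> list[Path]:
    """Write per-effect, per-split weight tables, subject score tables (when
    the dataset is supplied), and a machine-readable ``summary.json``.

    File naming is deterministic: ``effect{k}_split{j}_weights_{view}.csv``
    and ``effect{k}_split{j}_scores.csv``.
    """
    if not results:
        raise ValueError("no results to report")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    summary: dict = {"effects": []}
    for res in results:
        effect_entry = {
            "effect_index": res.effect_index,
            "significant": bool(res.significant),
            "n_splits_below_alpha": res.n_splits_below_alpha,
            "best_split_index": res.per_split[res.best_split_index].split_index,
            "splits": [],
        }
        for s in res.per_split:
            k, j = res.effect_index, s.split_index
            if not np.any(s.model.u) or not np.any(s.model.v):
                logger.warning("effect %d split %d has an all-zero weight vector", k, j)
            for tag, weights, names in (
                ("x", s.model.u, data.x.feature_names if data else None),
                ("y", s.model.v, data.y.feature_names if data else None),
            ):
                path = out / f"effect{k}_split{j}_weights_{tag}.csv"
                names = names or [f"{tag}{i + 1}" for i in range(len(weights))]
                pd.DataFrame({"feature_name": names, "weight": weights}).to_csv(
                    path, index=False, float_format="%.17g"
                )
                written.append(path)
            if data is not None:
                xc = data.x.values - data.x.values.mean(axis=0)
                yc = data.y.values - data.y.values.mean(axis=0)
                path = out / f"effect{k}_split{j}_scores.csv"
                pd.DataFrame(
                    {
                        "sample_id": data.x.sample_ids,
                        "x_score": xc @ s.model.u,
                        "y_score": yc @ s.model.v,
                    }
                ).to_csv(path, index=False, float_format="%.17g")
                written.append(path)
            effect_entry["splits"].append(
                {
                    "split_index": s.split_index,
                    "holdout_correlation": float(s.holdout_correlation),
                    "p_value": float(s.p_value),
                    "stability": float(s.stability_at_chosen),
                    "train_correlation": float(s.model.train_correlation),
                    "chosen_hyperparams": _hyperparams_dict(s.chosen_hyperparams),
                }
            )
        summary["effects"].append(effect_entry)
    summary_path = out / "summary.json"
    with open(summary_path, "w") as fh:
        json.dump(summary, fh, indent=2)
    written.append(summary_path)
    return written


def load_summary(out_dir: Union[str, Path]) -> dict:
    with open(Path(out_dir) / "summary.json") as fh:
        return json.load(fh)


def summary_table(summary: dict) -> pd.DataFrame:
    """Flatten a summary dict into one row per (effect, split)."""
    rows = []
    for eff in summary["effects"]:
        for s in eff["splits"]:
            row = {
                "effect": eff["effect_index"],
                "split": s["split_index"],
                "holdout_correlation": s["holdout_correlation"],
                "p_value": s["p_value"],
                "stability": s["stability"],
                "significant": eff["significant"],
                "best_split": s["split_index"] == eff["best_split_index"],
            }
            row.update(s["chosen_hyperparams"])
            rows.append(row)
    return pd.DataFrame(rows)
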