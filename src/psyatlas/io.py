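"""Cohort CSV and SOM JSON round-trips.

Cohort tables use a fixed CSV header (``subject_id, item_01..item_NN, age,
sex, wb1_1..wb1_6, wb2_1..wb2_6, depressed, split``); SOM models serialize
to versioned JSON that preserves the codebook at full precision, so BMU
lookups are identical before and after a round-trip.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import COHORT_COLUMNS, item_columns, wb1_columns, wb2_columns
from .som import SOMConfig, SOMModel

__all__ = ["read_cohort", "write_cohort", "save_som", "load_som"]

SOM_FORMAT_VERSION = 1


def _schema_columns(n_items: int) -> list[str]:
    return (
        ["subject_id"]
        + item_columns(n_items)
        + ["age", "sex"]
        + wb1_columns()
        + wb2_columns()
        + ["depressed", "split"]
    )


def write_cohort(table: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort table with the fixed header."""
    n_items = sum(c.startswith("item_") for c in table.columns)
    cols = _schema_columns(n_items)
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"cohort table lacks required columns: {missing}")
    table[cols].to_csv(path, index=False)


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort CSV; schema violations name the column."""
    table = pd.read_csv(path)
    n_items = sum(c.startswith("item_") for c in table.columns)
    if n_items == 0:
        raise ValueError("no item_* columns found in cohort file")
    cols = _schema_columns(n_items)
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"cohort file lacks required columns: {missing}")
    numeric = item_columns(n_items) + ["age"] + wb1_columns() + wb2_columns()
    for c in numeric:
        if not np.issubdtype(table[c].dtype, np.number):
            raise ValueError(f"column {c!r} must be numeric")
        if table[c].isna().any():
            raise ValueError(f"column {c!r} contains missing values")
    bad_sex = set(table["sex"].unique()) - {"male", "female"}
    if bad_sex:
        raise ValueError(f"column 'sex' has unknown codes: {sorted(bad_sex)}")
    bad_split = set(table["split"].unique()) - {"train", "test"}
    if bad_split:
        raise ValueError(f"column 'split' has unknown codes: {sorted(bad_split)}")
    table["depressed"] = table["depressed"].astype(bool)
    return table[cols]


def save_som(model: SOMModel, path: str | Path) -> None:
    """Serialize a trained SOM to JSON (codebook at full precision)."""
    payload = {
        "format_version": SOM_FORMAT_VERSION,
        "config": {
            "width": model.config.width,
            "height": model.config.height,
            "sigma0": model.config.sigma0,
            "learning_rate0": model.config.learning_rate0,
            "neighborhood": model.config.neighborhood,
            "activation_distance": model.config.activation_distance,
            "n_iterations_per_epoch": model.config.n_iterations_per_epoch,
            "max_epochs": model.config.max_epochs,
            "convergence_tol": model.config.convergence_tol,
            "patience": model.config.patience,
            "seed": model.config.seed,
        },
        "feature_names": model.feature_names,
        "codebook": model.codebook.tolist(),
        "scaler_mean": model.scaler_mean.tolist(),
        "scaler_scale": model.scaler_scale.tolist(),
        "training_log": model.training_log,
        "initial_qe": model.initial_qe,
    }
    Path(path).write_text(json.dumps(payload))


def load_som(path: str | Path) -> SOMModel:
    """Load a SOM saved by :func:`save_som`."""
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise ValueError(f"cannot parse SOM file {path}: {e}") from e
    version = payload.get("format_version")
    if version != SOM_FORMAT_VERSION:
        raise ValueError(
            f"unsupported SOM format version {version!r} (expected {SOM_FORMAT_VERSION})"
        )
    config = SOMConfig(**payload["config"])
    return SOMModel(
        config=config,
        codebook=np.asarray(payload["codebook"], dtype=float),
        feature_names=list(payload["feature_names"]),
        scaler_mean=np.asarray(payload["scaler_mean"], dtype=float),
        scaler_scale=np.asarray(payload["scaler_scale"], dtype=float),
        training_log=list(payload["training_log"]),
        initial_qe=float(payload["initial_qe"]),
    )
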