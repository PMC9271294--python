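"""Overlaying cohorts on a trained SOM and clustering the codebook.

Once a cohort is mapped cell-by-cell (each subject to its BMU), per-cell
metadata can be aggregated: depressed / non-depressed counts and their odds
ratio, mean well-being per Ryff dimension, and percent male.  Hierarchical
clustering of the codebook (complete linkage, Euclidean distance) partitions
the map into psychotype clusters, summarised in a table of per-cluster
counts, depression odds and sex composition with a totals row.  Clusters are
re-labelled 1..k by descending depression odds, so "cluster 1" is always the
depression-prone region.

Odds are reported raw (n_depressed / n_nondepressed).  A cell with depressed
subjects but no non-depressed ones gets infinite odds flagged as capped;
unoccupied cells carry undefined (NaN) odds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import spearmanr

from .cohort import item_columns, wb1_columns, wb2_columns
from .som import SOMModel, map_samples

__all__ = [
    "map_cohort",
    "overlay",
    "cluster_codebook",
    "cluster_stats",
    "odds_wellbeing_correlation",
    "ClusterMap",
]


def map_cohort(model: SOMModel, cohort: pd.DataFrame) -> np.ndarray:
    """Assign each subject to the BMU of its item vector (deterministic)."""
    cols = item_columns(model.n_features)
    missing = [c for c in cols if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort lacks item columns matching the model: {missing}")
    if list(cols) != list(model.feature_names):
        # model trained on custom feature names: require exact match instead
        missing = [c for c in model.feature_names if c not in cohort.columns]
        if missing:
            raise ValueError(f"cohort lacks model features: {missing}")
        cols = list(model.feature_names)
    idx, _ = map_samples(model, cohort[cols].to_numpy(dtype=float))
    return idx


def overlay(
    assignments: np.ndarray,
    cohort: pd.DataFrame,
    model: SOMModel | None = None,
    n_cells: int | None = None,
    wellbeing_wave: str = "wb2",
) -> pd.DataFrame:
    """Aggregate per-cell metadata for a mapped cohort.

    Returns a DataFrame indexed by cell (0..n_cells-1) with columns
    ``n_depressed``, ``n_nondepressed``, ``odds``, ``odds_capped``,
    ``pct_male``, ``occupied`` and the six mean well-being scores of the
    chosen wave (``wb2`` follow-up by default, ``wb1`` baseline).
    """
    if len(cohort) == 0:
        raise ValueError("cannot overlay an empty cohort")
    assignments = np.asarray(assignments)
    if len(assignments) != len(cohort):
        raise ValueError(
            f"{len(assignments)} assignments for {len(cohort)} subjects"
        )
    if n_cells is None:
        if model is None:
            n_cells = int(assignments.max()) + 1
        else:
            n_cells = model.n_cells
    wb_cols = {"wb1": wb1_columns(), "wb2": wb2_columns()}[wellbeing_wave]

    dep = np.asarray(cohort["depressed"], dtype=bool)
    male = np.asarray(cohort["sex"]) == "male"

    n_dep = np.bincount(assignments[dep], minlength=n_cells)
    n_non = np.bincount(assignments[~dep], minlength=n_cells)
    n_tot = n_dep + n_non
    occupied = n_tot > 0

    with np.errstate(divide="ignore", invalid="ignore"):
        odds = np.where(occupied, n_dep / n_non, np.nan)
    capped = occupied & (n_non == 0)

    n_male = np.bincount(assignments[male], minlength=n_cells)
    with np.errstate(invalid="ignore"):
        pct_male = np.where(occupied, 100.0 * n_male / n_tot, np.nan)

    out = pd.DataFrame(
        {
            "n_depressed": n_dep,
            "n_nondepressed": n_non,
            "odds": odds,
            "odds_capped": capped,
            "pct_male": pct_male,
            "occupied": occupied,
        },
        index=pd.RangeIndex(n_cells, name="cell"),
    )
    wb = cohort[wb_cols].to_numpy(dtype=float)
    for j, col in enumerate(wb_cols):
        sums = np.bincount(assignments, weights=wb[:, j], minlength=n_cells)
        with np.errstate(invalid="ignore"):
            out[f"mean_{col}"] = np.where(occupied, sums / n_tot, np.nan)
    return out


@dataclass
class ClusterMap:
    """Cell -> cluster assignment from complete-linkage codebook clustering.

    ``labels`` holds raw 1..k dendrogram labels per cell; relabelling by
    depression odds happens in :func:`cluster_stats`, where an overlay is
    available.
    """

    labels: np.ndarray
    n_clusters: int
    linkage: str = "complete"
    metric: str = "euclidean"

    def cells_in(self, cluster: int) -> np.ndarray:
        return np.flatnonzero(self.labels == cluster)


def cluster_codebook(model: SOMModel, n_clusters: int = 3) -> ClusterMap:
    """Agglomerative clustering of codebook vectors, dendrogram cut at k.

    Complete linkage with Euclidean distance, matching the atlas design the
    package models.
    """
    if not 2 <= n_clusters <= model.n_cells:
        raise ValueError(
            f"n_clusters must be in [2, {model.n_cells}], got {n_clusters}"
        )
    Z = linkage(model.codebook, method="complete", metric="euclidean")
    labels = fcluster(Z, t=n_clusters, criterion="maxclust")
    return ClusterMap(labels=np.asarray(labels), n_clusters=n_clusters)


def _odds(n_dep: float, n_non: float) -> float:
    if n_non > 0:
        return n_dep / n_non
    return np.inf if n_dep > 0 else np.nan


def cluster_stats(clustermap: ClusterMap, cell_overlay: pd.DataFrame) -> pd.DataFrame:
    """Per-cluster summary (counts, odds, % male, mean well-being) + totals.

    Depressed / non-depressed counts are summed over each cluster's cells
    and the odds ratio is computed from the summed counts.  Rows are ordered
    and re-labelled ``cluster_1..k`` by descending depression odds (NaN odds
    sort last), followed by a ``total`` row equal to the column sums.
    """
    wb_cols = [c for c in cell_overlay.columns if c.startswith("mean_")]

    def wmean(values: pd.Series, weights: pd.Series) -> float:
        w = weights.to_numpy(dtype=float)
        v = values.to_numpy(dtype=float)
        mask = w > 0
        return float((v[mask] * w[mask]).sum() / w[mask].sum()) if mask.any() else np.nan

    rows = []
    for lab in range(1, clustermap.n_clusters + 1):
        cells = clustermap.cells_in(lab)
        sub = cell_overlay.iloc[cells]
        n_dep = int(sub["n_depressed"].sum())
        n_non = int(sub["n_nondepressed"].sum())
        counts = sub["n_depressed"] + sub["n_nondepressed"]
        row = {
            "raw_label": lab,
            "n_cells": len(cells),
            "n_depressed": n_dep,
            "n_nondepressed": n_non,
            "odds": _odds(n_dep, n_non),
            "pct_male": wmean(sub["pct_male"], counts),
        }
        for c in wb_cols:
            row[c] = wmean(sub[c], counts)
        rows.append(row)

    stats = pd.DataFrame(rows)
    order = stats["odds"].rank(ascending=False, na_option="bottom", method="first")
    stats = stats.iloc[np.argsort(order.to_numpy(), kind="stable")].reset_index(drop=True)
    stats.index = pd.Index(
        [f"cluster_{i + 1}" for i in range(len(stats))], name="cluster"
    )

    n_dep = int(stats["n_depressed"].sum())
    n_non = int(stats["n_nondepressed"].sum())
    counts = stats["n_depressed"] + stats["n_nondepressed"]
    total = {
        "raw_label": -1,
        "n_cells": int(stats["n_cells"].sum()),
        "n_depressed": n_dep,
        "n_nondepressed": n_non,
        "odds": _odds(n_dep, n_non),
        "pct_male": wmean(stats["pct_male"], counts),
    }
    for c in wb_cols:
        total[c] = wmean(stats[c], counts)
    stats.loc["total"] = total
    return stats


def odds_wellbeing_correlation(cell_overlay: pd.DataFrame) -> pd.DataFrame:
    """Spearman correlation of per-cell depression odds with mean well-being.

    Computed across occupied cells with finite odds, one row per well-being
    dimension present in the overlay, with two-sided p-values.  Degenerate
    inputs (constant odds or constant well-being) yield NaN correlation.
    """
    usable = cell_overlay["occupied"] & np.isfinite(cell_overlay["odds"])
    sub = cell_overlay[usable]
    if len(sub) < 3:
        raise ValueError(
            f"need >= 3 occupied cells with defined odds, got {len(sub)}"
        )
    wb_cols = [c for c in cell_overlay.columns if c.startswith("mean_")]
    rows = []
    for c in wb_cols:
        if sub["odds"].nunique() < 2 or sub[c].nunique() < 2:
            rho, p = np.nan, np.nan
        else:
            rho, p = spearmanr(sub["odds"], sub[c])
        rows.append({"dimension": c.removeprefix("mean_"), "rho": rho, "p_value": p})
    return pd.DataFrame(rows).set_index("dimension")
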