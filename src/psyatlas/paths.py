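"""Shortest self-improvement paths across the SOM.

The trained map is treated as a weighted graph: cells are nodes, edges
connect 8-neighbors on the grid, and each edge is weighted by the Euclidean
distance between the two codebook vectors.  The weighted shortest path from
the depression hotspot (the occupied cell with maximal depression odds) to
the most stable cell (minimal odds) is computed with the Bellman-Ford
algorithm and read out as per-feature trajectories: the codebook values, in
original item units, of the cells along the path.  Ranking the features by
their signed endpoint change yields the top attitude-change recommendations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .som import SOMModel

__all__ = [
    "build_graph",
    "shortest_path",
    "select_endpoints",
    "rank_feature_changes",
    "PathResult",
]

_REL_TOL = 1e-9


@dataclass
class PathResult:
    """An ordered cell path with its weighted length and feature read-out."""

    cells: list[int]
    coords: list[tuple[int, int]]  # (row, col), 0-based, row-major grid
    total_length: float
    feature_trajectories: pd.DataFrame  # steps x features, original units

    @property
    def n_steps(self) -> int:
        return len(self.cells)


def build_graph(model: SOMModel) -> nx.Graph:
    """Weighted 8-connectivity grid graph over the SOM cells.

    Node ids are 0-based row-major cell indices carrying ``row``/``col``
    attributes; edge weights are Euclidean distances between the incident
    cells' codebook vectors (scaled space), hence non-negative.
    """
    h, w = model.config.height, model.config.width
    cb = model.codebook
    g = nx.Graph()
    for cell in range(model.n_cells):
        g.add_node(cell, row=cell // w, col=cell % w)
    for r in range(h):
        for c in range(w):
            u = r * w + c
            for dr, dc in ((0, 1), (1, -1), (1, 0), (1, 1)):
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w:
                    v = rr * w + cc
                    g.add_edge(u, v, weight=float(np.linalg.norm(cb[u] - cb[v])))
    return g


def _bellman_ford(graph: nx.Graph, source: int) -> dict[int, float]:
    """Textbook Bellman-Ford distances from ``source`` (undirected graph)."""
    dist = {n: math.inf for n in graph.nodes}
    dist[source] = 0.0
    edges = [(u, v, d["weight"]) for u, v, d in graph.edges(data=True)]
    for _ in range(graph.number_of_nodes() - 1):
        changed = False
        for u, v, w in edges:
            if dist[u] + w < dist[v]:
                dist[v] = dist[u] + w
                changed = True
            if dist[v] + w < dist[u]:
                dist[u] = dist[v] + w
                changed = True
        if not changed:
            break
    return dist


def shortest_path(
    graph: nx.Graph,
    source: int,
    target: int,
    model: SOMModel | None = None,
) -> PathResult:
    """Bellman-Ford minimal-weight path from source to target.

    Among equally short paths the lexicographically smallest cell sequence
    is returned (greedy lowest-index choice along cells consistent with the
    distance-to-target field).  ``source == target`` gives a single-cell
    path of length 0.  If ``model`` is given, per-feature trajectories in
    original units are attached.
    """
    for cell in (source, target):
        if cell not in graph:
            raise ValueError(f"cell {cell} is not on the grid")
    dist_to_target = _bellman_ford(graph, target)
    total = dist_to_target[source]
    if math.isinf(total):
        raise ValueError(f"no path between cells {source} and {target}")

    cells = [source]
    current = source
    while current != target:
        best = None
        for v in sorted(graph.neighbors(current)):
            w = graph.edges[current, v]["weight"]
            remaining = dist_to_target[current] - w
            if math.isclose(dist_to_target[v], remaining, rel_tol=_REL_TOL, abs_tol=1e-12):
                best = v
                break
        if best is None:  # numerical safety net; cannot trigger on consistent fields
            raise RuntimeError("path reconstruction failed")
        cells.append(best)
        current = best

    coords = []
    traj = pd.DataFrame()
    if model is not None:
        coords = [tuple(int(x) for x in np.divmod(c, model.config.width)) for c in cells]
        traj = pd.DataFrame(
            model.codebook_original[cells],
            columns=model.feature_names,
            index=pd.RangeIndex(len(cells), name="step"),
        )
    return PathResult(
        cells=cells,
        coords=coords,
        total_length=float(total),
        feature_trajectories=traj,
    )


def select_endpoints(cell_overlay: pd.DataFrame) -> tuple[int, int]:
    """(hotspot, stable) cells by extreme depression odds.

    Hotspot: occupied cell with maximal odds (capped/infinite odds allowed);
    ties broken by most depressed subjects, then lowest cell index.  Stable:
    occupied cell with minimal odds; ties by most non-depressed subjects,
    then lowest index.
    """
    occ = cell_overlay[cell_overlay["occupied"]]
    with_dep = occ[occ["n_depressed"] > 0]
    with_non = occ[occ["n_nondepressed"] > 0]
    if len(with_dep) == 0 or len(with_non) == 0:
        raise ValueError("need at least one occupied cell of each label")

    odds = occ["odds"].to_numpy(dtype=float)
    hot_pool = occ[odds == np.max(odds)]
    hotspot = int(
        hot_pool[hot_pool["n_depressed"] == hot_pool["n_depressed"].max()].index.min()
    )

    stable_pool = occ[odds == np.min(odds)]
    stable = int(
        stable_pool[
            stable_pool["n_nondepressed"] == stable_pool["n_nondepressed"].max()
        ].index.min()
    )
    return hotspot, stable


def rank_feature_changes(
    path: PathResult, k: int = 5, mode: str = "endpoint"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Top-k decreasing and increasing features along a path.

    ``endpoint`` mode (default) scores each feature by its signed change
    between the last and first path cell, in original item units; ``range``
    mode scores by max minus min along the whole trajectory, signed by the
    endpoint direction.  Features with exactly zero delta are dropped.
    Returns (decreasing, increasing) frames sorted by |delta|, each with the
    per-step trajectory attached as a list column for plotting.
    """
    traj = path.feature_trajectories
    if path.n_steps < 2:
        raise ValueError("path must contain at least 2 cells")
    if traj.empty:
        raise ValueError("path carries no feature trajectories (pass model to shortest_path)")
    if k > traj.shape[1]:
        raise ValueError(f"k={k} exceeds the {traj.shape[1]} available features")
    if mode not in ("endpoint", "range"):
        raise ValueError(f"unknown ranking mode {mode!r}")

    endpoint = traj.iloc[-1] - traj.iloc[0]
    if mode == "endpoint":
        delta = endpoint
    else:
        delta = (traj.max() - traj.min()) * np.sign(endpoint).replace(0, 1)

    table = pd.DataFrame(
        {
            "feature": traj.columns,
            "delta": delta.to_numpy(),
            "trajectory": [traj[c].to_list() for c in traj.columns],
        }
    )
    table = table[table["delta"] != 0]
    table = table.reindex(table["delta"].abs().sort_values(ascending=False, kind="stable").index)
    decreasing = table[table["delta"] < 0].head(k).reset_index(drop=True)
    increasing = table[table["delta"] > 0].head(k).reset_index(drop=True)
    return decreasing, increasing
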