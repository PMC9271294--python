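"""End-to-end atlas pipeline: cohort -> SOM -> overlay -> clusters -> path.

``run_pipeline`` chains the stages: simulate (or load) a cohort, train the
SOM on the non-depressed training partition, map the test cohort, aggregate
the per-cell overlay, cluster the codebook, pick the depression hotspot and
the most stable cell, and compute the shortest path with its ranked
attitude-change recommendations.  Predictor training and the elastic-net
importance comparison are optional stages.  Every artifact is written to the
output directory together with a manifest of seeds and stage timings, and a
fixed seed makes the whole run bit-reproducible.

The training partition must contain no depressed subjects; a cohort that
violates this is refused.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .atlas import cluster_codebook, cluster_stats, map_cohort, overlay
from .cohort import CohortSpec, generate_cohort
from .io import save_som, write_cohort
from .paths import build_graph, rank_feature_changes, select_endpoints, shortest_path
from .predictors import PredictorConfig, predict, train_predictor
from .selection import en_importance
from .som import SOMConfig, train_som

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]

log = logging.getLogger("psyatlas")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class RunConfig:
    """Configuration of one end-to-end run."""

    cohort_path: str | None = None  # None -> simulate from cohort_spec
    cohort_spec: CohortSpec = field(default_factory=CohortSpec)
    som_config: SOMConfig = field(default_factory=SOMConfig)
    n_clusters: int = 3
    top_k: int = 5
    run_predictors: bool = False
    run_importance: bool = False
    predictor_config: PredictorConfig | None = None
    out_dir: str | None = None
    seed: int = 0


def _stage(name: str, manifest: dict):
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is None:
                # timings go to the log only, so manifests of identical runs
                # compare bit-equal
                manifest["stages"].append(name)
                log.info("stage=%s seconds=%.3f", name, dt)
                return False
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    return _Ctx()


def run_pipeline(config: RunConfig) -> dict:
    """Run the full atlas pipeline; returns the report bundle as a dict."""
    manifest = {
        "psyatlas_version": __version__,
        "seed": config.seed,
        "stages": [],
    }
    bundle: dict = {"manifest": manifest}
    root = np.random.SeedSequence(config.seed)
    seeds = {name: int(s.generate_state(1)[0] % (2**31 - 1))
             for name, s in zip(("cohort", "som", "predictor"), root.spawn(3))}
    manifest["stage_seeds"] = seeds

    with _stage("cohort", manifest):
        if config.cohort_path is not None:
            from .io import read_cohort

            cohort = read_cohort(config.cohort_path)
        else:
            spec = config.cohort_spec
            spec = CohortSpec(**{**spec.__dict__, "seed": seeds["cohort"]})
            cohort = generate_cohort(spec)
        train = cohort[cohort["split"] == "train"]
        test = cohort[cohort["split"] == "test"]
        if train["depressed"].any():
            raise ValueError(
                f"training cohort contains {int(train['depressed'].sum())} "
                "depressed subject(s); the map must be trained on "
                "non-depressed respondents only"
            )
        if len(train) == 0 or len(test) == 0:
            raise ValueError("both train and test partitions must be non-empty")
    bundle["cohort"] = cohort

    item_cols = [c for c in cohort.columns if c.startswith("item_")]
    with _stage("train_som", manifest):
        som_cfg = SOMConfig(**{**config.som_config.__dict__, "seed": seeds["som"]})
        model = train_som(train[item_cols].to_numpy(dtype=float), som_cfg, item_cols)
    bundle["som"] = model

    with _stage("overlay", manifest):
        assignments = map_cohort(model, test)
        cells = overlay(assignments, test, model=model)
    bundle["assignments"] = assignments
    bundle["overlay"] = cells

    with _stage("cluster", manifest):
        clusters = cluster_codebook(model, config.n_clusters)
        stats = cluster_stats(clusters, cells)
    bundle["clusters"] = clusters
    bundle["cluster_stats"] = stats

    with _stage("path", manifest):
        hotspot, stable = select_endpoints(cells)
        graph = build_graph(model)
        path = shortest_path(graph, hotspot, stable, model=model)
        decreasing, increasing = rank_feature_changes(path, k=config.top_k)
    bundle["endpoints"] = (hotspot, stable)
    bundle["path"] = path
    bundle["recommendations"] = {"decrease": decreasing, "increase": increasing}

    if config.run_predictors or config.run_importance:
        with _stage("predictors", manifest):
            pcfg = config.predictor_config or PredictorConfig(task="wellbeing6")
            pcfg = PredictorConfig(**{**pcfg.__dict__, "seed": seeds["predictor"]})
            wb_model, wb_report = train_predictor(cohort, pcfg)
        bundle["predictor_report"] = wb_report

        if config.run_importance:
            with _stage("importance", manifest):
                train_pred = wb_report.oof_predictions
                entries = [
                    en_importance(
                        train.loc[train_pred.index],
                        train_pred[f"wb2_{d + 1}"],
                        d,
                        seed=seeds["predictor"],
                    )
                    for d in range(6)
                ]
            bundle["importance"] = entries

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_cohort(cohort, out / "cohort.csv")
        save_som(model, out / "som.json")
        cells.to_csv(out / "overlay.csv")
        stats.to_csv(out / "cluster_stats.csv")
        path_json = {
            "cells": path.cells,
            "coords": path.coords,
            "total_length": path.total_length,
            "hotspot": hotspot,
            "stable": stable,
        }
        (out / "path.json").write_text(json.dumps(path_json, indent=2))
        path.feature_trajectories.to_csv(out / "trajectories.csv")
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return bundle
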