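"""Shortest self-improvement path across the map, with ranked recommendations.

The path runs from the depression hotspot (occupied cell with the highest
depressed/non-depressed odds) to the most stable cell (lowest odds), moving
only between grid neighbors and weighting each step by the codebook
distance.  The features that change the most between the endpoints are the
primary attitude-change recommendations.
"""

from psyatlas import (
    CohortSpec,
    SOMConfig,
    RunConfig,
    rank_feature_changes,
    run_pipeline,
)

bundle = run_pipeline(
    RunConfig(cohort_spec=CohortSpec(), som_config=SOMConfig(width=12, height=12), seed=3)
)
hotspot, stable = bundle["endpoints"]
path = bundle["path"]
print(f"hotspot cell {hotspot} -> stable cell {stable}: "
      f"{path.n_steps} cells, weighted length {path.total_length:.2f}")
print("route (row, col):", path.coords)

decreasing, increasing = rank_feature_changes(path, k=5)
print("\ntop-5 attitudes to dial down (higher in the depression-prone region):")
print(decreasing[["feature", "delta"]].round(2).to_string(index=False))
print("\ntop-5 attitudes to build up (higher in the stable region):")
print(increasing[["feature", "delta"]].round(2).to_string(index=False))
print("\neach delta is the change in codebook value (original 1-7 item units) "
      "between the two ends of the path.")
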