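"""Cohort overlays, codebook clustering and cluster summary tables."""

import numpy as np
import pandas as pd
import pytest
from sklearn.cluster import AgglomerativeClustering

from psyatlas import (
    cluster_codebook,
    cluster_stats,
    map_cohort,
    odds_wellbeing_correlation,
    overlay,
)
from psyatlas.atlas import ClusterMap
from psyatlas.cohort import item_columns, wb1_columns, wb2_columns
from tests.test_som import make_model


def tiny_cohort(items, depressed, sex=None):
    """Cohort frame from an item matrix (n x p) for overlay tests."""
    items = np.asarray(items, dtype=float)
    n, p = items.shape
    df = pd.DataFrame(items, columns=item_columns(p))
    df.insert(0, "subject_id", np.arange(n))
    df["age"] = 50.0
    df["sex"] = sex if sex is not None else ["female"] * n
    for c in wb1_columns() + wb2_columns():
        df[c] = 5.0
    df["depressed"] = np.asarray(depressed, dtype=bool)
    df["split"] = "test"
    return df


class TestMapCohort:
    def test_subject_on_codebook_vector_hits_that_cell(self, rng):
        codebook = rng.normal(size=(16, 4))
        model = make_model(codebook, 4, 4, feature_names=item_columns(4))
        cohort = tiny_cohort(codebook[[7]], [False])
        assert map_cohort(model, cohort)[0] == 7

    def test_mapping_is_deterministic(self, rng):
        model = make_model(rng.normal(size=(16, 4)), 4, 4, feature_names=item_columns(4))
        cohort = tiny_cohort(rng.normal(size=(30, 4)), np.zeros(30))
        a = map_cohort(model, cohort)
        b = map_cohort(model, cohort)
        np.testing.assert_array_equal(a, b)

    def test_matches_per_subject_brute_force(self, rng):
        codebook = rng.normal(size=(16, 4))
        model = make_model(codebook, 4, 4, feature_names=item_columns(4))
        items = rng.normal(size=(30, 4))
        cohort = tiny_cohort(items, np.zeros(30))
        got = map_cohort(model, cohort)
        for i, x in enumerate(items):
            assert got[i] == int(np.argmin([np.linalg.norm(x - c) for c in codebook]))

    def test_feature_mismatch_rejected(self, rng):
        model = make_model(rng.normal(size=(4, 6)), 2, 2, feature_names=item_columns(6))
        cohort = tiny_cohort(rng.normal(size=(5, 4)), np.zeros(5))
        with pytest.raises(ValueError, match="item"):
            map_cohort(model, cohort)


class TestOverlay:
    def test_counts_conserved_and_occupancy(self, atlas_bundle):
        ov = atlas_bundle["overlay"]
        test = atlas_bundle["cohort"].query("split == 'test'")
        assert ov["n_depressed"].sum() == int(test["depressed"].sum())
        assert ov["n_nondepressed"].sum() == int((~test["depressed"]).sum())
        assert (ov.loc[~ov["occupied"], ["n_depressed", "n_nondepressed"]] == 0).all().all()
        assert ov.loc[~ov["occupied"], "odds"].isna().all()

    def test_odds_of_printed_counts(self):
        """71 depressed vs 33 non-depressed in a region gives odds 2.15."""
        items = np.zeros((104, 2))
        cohort = tiny_cohort(items, [True] * 71 + [False] * 33)
        ov = overlay(np.zeros(104, dtype=int), cohort, n_cells=4)
        assert round(ov.loc[0, "odds"], 2) == 2.15

    def test_no_depressed_cell_has_zero_odds(self):
        cohort = tiny_cohort(np.zeros((5, 2)), [False] * 5)
        ov = overlay(np.zeros(5, dtype=int), cohort, n_cells=2)
        assert ov.loc[0, "odds"] == 0.0
        assert not ov.loc[0, "odds_capped"]

    def test_depressed_only_cell_odds_capped_infinite(self):
        cohort = tiny_cohort(np.zeros((3, 2)), [True] * 3)
        ov = overlay(np.zeros(3, dtype=int), cohort, n_cells=2)
        assert np.isinf(ov.loc[0, "odds"])
        assert bool(ov.loc[0, "odds_capped"])

    def test_study_composition_gives_overall_odds_051(self):
        cohort = tiny_cohort(np.zeros((1173, 2)), [True] * 394 + [False] * 779)
        ov = overlay(np.zeros(1173, dtype=int), cohort, n_cells=1)
        assert round(ov.loc[0, "odds"], 2) == 0.51

    def test_empty_cohort_rejected(self):
        cohort = tiny_cohort(np.zeros((1, 2)), [False]).iloc[:0]
        with pytest.raises(ValueError, match="empty"):
            overlay(np.array([], dtype=int), cohort, n_cells=2)


class TestClusterCodebook:
    def test_three_planted_blobs_recovered(self, rng):
        centers = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
        owner = rng.integers(0, 3, size=16)
        codebook = centers[owner] + rng.normal(0, 0.1, size=(16, 2))
        model = make_model(codebook, 4, 4)
        cm = cluster_codebook(model, 3)
        for blob in range(3):
            labels = cm.labels[owner == blob]
            assert len(set(labels)) == 1
        assert len(set(cm.labels)) == 3

    def test_singleton_limit(self, rng):
        model = make_model(rng.normal(size=(6, 2)), 3, 2)
        cm = cluster_codebook(model, 6)
        assert sorted(cm.labels) == [1, 2, 3, 4, 5, 6]

    def test_matches_reference_agglomerative_partition(self, rng):
        codebook = rng.normal(size=(16, 3))
        model = make_model(codebook, 4, 4)
        cm = cluster_codebook(model, 3)
        ref = AgglomerativeClustering(n_clusters=3, linkage="complete").fit_predict(codebook)
        # same partition up to label permutation
        pairs = {tuple(sorted({a, b})) for a in range(3) for b in range(3)}
        for i in range(16):
            for j in range(i + 1, 16):
                assert (cm.labels[i] == cm.labels[j]) == (ref[i] == ref[j])

    def test_out_of_range_k_rejected(self, rng):
        model = make_model(rng.normal(size=(4, 2)), 2, 2)
        for k in (1, 5):
            with pytest.raises(ValueError, match="n_clusters"):
                cluster_codebook(model, k)


def overlay_from_counts(cells_per_cluster, dep, non, n_cells):
    """Build an overlay frame placing each cluster's counts in its cells."""
    ov = pd.DataFrame(
        {
            "n_depressed": 0,
            "n_nondepressed": 0,
            "odds": np.nan,
            "odds_capped": False,
            "pct_male": np.nan,
            "occupied": False,
            "mean_wb2_1": np.nan,
        },
        index=pd.RangeIndex(n_cells, name="cell"),
    )
    labels = np.zeros(n_cells, dtype=int)
    start = 0
    for k, (size, d, m) in enumerate(zip(cells_per_cluster, dep, non), start=1):
        labels[start : start + size] = k
        ov.loc[start, "n_depressed"] = d
        ov.loc[start, "n_nondepressed"] = m
        ov.loc[start, "occupied"] = d + m > 0
        ov.loc[start, "odds"] = d / m if m else np.nan
        ov.loc[start, "pct_male"] = 40.0
        ov.loc[start, "mean_wb2_1"] = 5.0
        start += size
    return ov, ClusterMap(labels=labels, n_clusters=len(cells_per_cluster))


class TestClusterStats:
    def test_published_contingency_counts_reproduce_odds(self):
        """53/244/328 cells with (71,33), (179,261), (144,485) subjects."""
        ov, cm = overlay_from_counts(
            [53, 244, 328], dep=[71, 179, 144], non=[33, 261, 485], n_cells=625
        )
        stats = cluster_stats(cm, ov)
        assert stats.loc["cluster_1", "odds"] == pytest.approx(2.15, abs=0.005)
        assert stats.loc["cluster_2", "odds"] == pytest.approx(0.69, abs=0.005)
        assert stats.loc["cluster_3", "odds"] == pytest.approx(0.30, abs=0.005)
        assert stats.loc["total", "odds"] == pytest.approx(0.51, abs=0.005)
        assert list(stats["n_cells"]) == [53, 244, 328, 625]

    def test_relabeling_orders_by_descending_odds(self):
        ov, cm = overlay_from_counts([2, 2], dep=[1, 30], non=[10, 10], n_cells=4)
        stats = cluster_stats(cm, ov)
        assert stats.loc["cluster_1", "odds"] == pytest.approx(3.0)
        assert stats.loc["cluster_2", "odds"] == pytest.approx(0.1)

    def test_empty_cluster_reports_undefined_odds(self):
        ov, cm = overlay_from_counts([2, 2], dep=[5, 0], non=[5, 0], n_cells=4)
        stats = cluster_stats(cm, ov)
        assert stats.loc["cluster_2", "n_depressed"] == 0
        assert np.isnan(stats.loc["cluster_2", "odds"])

    def test_totals_row_equals_column_sums(self, atlas_bundle):
        stats = atlas_bundle["cluster_stats"]
        per_cluster = stats.drop(index="total")
        for col in ("n_cells", "n_depressed", "n_nondepressed"):
            assert stats.loc["total", col] == per_cluster[col].sum()

    def test_planted_cohort_reproduces_depression_prone_cluster(self, atlas_bundle):
        """Max-odds cluster: odds > 1 on a map whose overall odds < 1."""
        stats = atlas_bundle["cluster_stats"]
        assert stats.loc["cluster_1", "odds"] > 1.0
        assert stats.loc["total", "odds"] < 1.0
        n_cells_avg = stats.loc["total", "n_cells"] / (len(stats) - 1)
        assert stats.loc["cluster_1", "n_cells"] < n_cells_avg


class TestOddsWellbeingCorrelation:
    def _frame(self, odds, wb):
        n = len(odds)
        return pd.DataFrame(
            {
                "n_depressed": 1,
                "n_nondepressed": 1,
                "odds": odds,
                "odds_capped": False,
                "pct_male": 50.0,
                "occupied": True,
                "mean_wb2_1": wb,
            },
            index=pd.RangeIndex(n, name="cell"),
        )

    def test_perfect_negative_relation(self):
        odds = np.array([0.1, 0.5, 1.0, 2.0, 4.0])
        out = odds_wellbeing_correlation(self._frame(odds, -odds))
        assert out.loc["wb2_1", "rho"] == pytest.approx(-1.0)

    def test_constant_odds_reported_undefined(self):
        out = odds_wellbeing_correlation(self._frame(np.ones(5), np.arange(5.0)))
        assert np.isnan(out.loc["wb2_1", "rho"])

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError, match="3"):
            odds_wellbeing_correlation(self._frame(np.array([0.5, 1.0]), np.zeros(2)))

    def test_planted_cohort_all_dimensions_significantly_negative(self, atlas_bundle):
        out = odds_wellbeing_correlation(atlas_bundle["overlay"])
        assert (out["rho"] < 0).all()
        assert (out["p_value"] < 0.001).all()
        assert len(out) == 6
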