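"""SOM training, BMU lookup, quantization error and U-matrix.

Brute-force oracles recompute BMUs and neighbor averages cell by cell; the
training cross-check compares quantization error against an independent,
minimal online-Kohonen oracle implemented below (separate code path from the
package).
"""

import numpy as np
import pytest
from scipy.stats import spearmanr

from psyatlas import SOMConfig, SOMModel, find_bmu, quantization_error, train_som, u_matrix
from psyatlas.som import map_samples


def make_model(codebook, width, height, feature_names=None):
    """A model with an identity scaler, for direct codebook-level tests."""
    codebook = np.asarray(codebook, dtype=float)
    p = codebook.shape[1]
    return SOMModel(
        config=SOMConfig(width=width, height=height),
        codebook=codebook,
        feature_names=feature_names or [f"f{i}" for i in range(p)],
        scaler_mean=np.zeros(p),
        scaler_scale=np.ones(p),
    )


def reference_som_qe(data, width, height, sigma0, lr0, n_iterations, seed, horizon=None):
    """Minimal independent online-Kohonen oracle (loop implementation).

    ``horizon`` is the decay schedule length (defaults to ``n_iterations``),
    so the oracle can be run with the same sigma/learning-rate trajectory as
    a model that stopped early on convergence.
    """
    rng = np.random.default_rng(seed)
    horizon = horizon or n_iterations
    n, p = data.shape
    codebook = rng.uniform(data.min(0), data.max(0), size=(height * width, p))
    coords = np.array([(i // width, i % width) for i in range(height * width)])
    for t in range(n_iterations):
        x = data[rng.integers(0, n)]
        bmu = min(range(len(codebook)), key=lambda c: np.sum((codebook[c] - x) ** 2))
        decay = 1.0 + t / (horizon / 2.0)
        sigma, lr = sigma0 / decay, lr0 / decay
        for c in range(len(codebook)):
            g2 = np.sum((coords[c] - coords[bmu]) ** 2)
            h = lr * np.exp(-g2 / (2 * sigma**2))
            codebook[c] += h * (x - codebook[c])
    dists = [
        min(np.linalg.norm(x - codebook[c]) for c in range(len(codebook))) for x in data
    ]
    return float(np.mean(dists))


class TestTraining:
    def test_single_sample_single_cell_fixed_point(self):
        data = np.array([[2.0, -1.0, 0.5]])
        cfg = SOMConfig(width=1, height=1, max_epochs=50, seed=0)
        model = train_som(data, cfg)
        # z-scoring a single sample gives the zero vector; the lone cell
        # converges onto it and the quantization error vanishes
        assert quantization_error(model, data) < 1e-6
        np.testing.assert_allclose(model.codebook_original[0], data[0], atol=1e-4)

    def test_identical_config_and_data_identical_codebooks(self, rng):
        data = rng.normal(size=(80, 4))
        cfg = SOMConfig(width=4, height=3, seed=5, max_epochs=10)
        a = train_som(data, cfg)
        b = train_som(data, cfg)
        np.testing.assert_array_equal(a.codebook, b.codebook)
        assert a.training_log == b.training_log

    def test_two_blob_training_beats_initial_codebook(self, rng):
        blobs = np.vstack(
            [rng.normal(-4, 0.5, size=(100, 3)), rng.normal(4, 0.5, size=(100, 3))]
        )
        cfg = SOMConfig(width=5, height=5, seed=1)
        model = train_som(blobs, cfg)
        assert quantization_error(model, blobs) < model.initial_qe

    def test_quantization_error_matches_independent_som_oracle(self, rng):
        blobs = np.vstack(
            [rng.normal(-4, 0.5, size=(100, 3)), rng.normal(4, 0.5, size=(100, 3))]
        )
        cfg = SOMConfig(width=5, height=5, seed=1)
        model = train_som(blobs, cfg)
        scaled = model.scale(blobs)
        oracle_qe = reference_som_qe(
            scaled, 5, 5, sigma0=cfg.sigma0, lr0=cfg.learning_rate0,
            n_iterations=200 * len(model.training_log), seed=2,
            horizon=200 * cfg.max_epochs,
        )
        ours = quantization_error(model, blobs)
        assert ours == pytest.approx(oracle_qe, rel=0.2)

    def test_convergence_log_stops_improving(self, rng):
        data = rng.normal(size=(150, 4))
        cfg = SOMConfig(width=6, height=6, seed=3, convergence_tol=1e-4, patience=5)
        model = train_som(data, cfg)
        log = model.training_log
        if cfg.patience < len(log) < cfg.max_epochs:  # stopped by convergence, not the cap
            best_before = min(log[: -cfg.patience])
            assert all(best_before - q <= cfg.convergence_tol for q in log[-cfg.patience :])

    def test_topology_preserved_on_planted_line(self):
        rng = np.random.default_rng(12)
        t = np.linspace(0, 1, 200)
        line = np.outer(t, [3.0, -2.0, 1.0, 4.0]) + rng.normal(0, 0.05, size=(200, 4))
        model = train_som(line, SOMConfig(width=10, height=10, seed=12))
        cells, _ = map_samples(model, line)
        rows, cols = model.grid_coords(cells)
        rho = max(
            abs(spearmanr(t, proj).statistic)
            for proj in (rows, cols, rows + cols, rows - cols)
        )
        assert rho >= 0.8

    @pytest.mark.parametrize(
        "data, err",
        [
            (np.empty((0, 3)), "non-empty"),
            (np.array([[1.0, np.nan]]), "non-finite"),
        ],
    )
    def test_bad_data_rejected(self, data, err):
        with pytest.raises(ValueError, match=err):
            train_som(data, SOMConfig(width=2, height=2))

    def test_feature_name_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="feature_names"):
            train_som(rng.normal(size=(10, 3)), SOMConfig(width=2, height=2), ["a", "b"])


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"sigma0": 0.0},
            {"learning_rate0": 0.0},
            {"learning_rate0": 1.5},
            {"width": 0},
            {"neighborhood": "bubble"},
            {"activation_distance": "cosine"},
        ],
    )
    def test_invalid_config(self, kwargs):
        with pytest.raises(ValueError):
            SOMConfig(**kwargs)


class TestBMU:
    def test_exact_codebook_match(self, rng):
        codebook = rng.normal(size=(9, 4))
        model = make_model(codebook, 3, 3)
        cell, dist = find_bmu(model, codebook[5])
        assert (cell, dist) == (5, 0.0)

    def test_one_cell_map_always_cell_zero(self, rng):
        model = make_model(rng.normal(size=(1, 3)), 1, 1)
        for _ in range(5):
            assert find_bmu(model, rng.normal(size=3))[0] == 0

    def test_matches_brute_force_argmin(self, rng):
        codebook = rng.normal(size=(9, 4))
        model = make_model(codebook, 3, 3)
        for sample in rng.normal(size=(50, 4)):
            dists = [np.linalg.norm(sample - c) for c in codebook]
            expected = int(np.argmin(dists))
            cell, d = find_bmu(model, sample)
            assert cell == expected
            assert d == pytest.approx(min(dists))

    def test_tie_breaks_to_lowest_index(self):
        codebook = np.array([[1.0, 0.0], [1.0, 0.0], [5.0, 5.0], [1.0, 0.0]])
        model = make_model(codebook, 2, 2)
        assert find_bmu(model, [0.0, 0.0])[0] == 0

    def test_every_codebook_vector_self_matches(self, rng):
        codebook = rng.normal(size=(12, 5))
        model = make_model(codebook, 4, 3)
        for k in range(12):
            assert find_bmu(model, codebook[k]) == (k, 0.0)

    def test_length_mismatch_rejected(self, rng):
        model = make_model(rng.normal(size=(4, 3)), 2, 2)
        with pytest.raises(ValueError, match="shape"):
            find_bmu(model, np.zeros(5))


class TestQuantizationError:
    def test_data_equal_codebook_gives_zero(self, rng):
        codebook = rng.normal(size=(6, 3))
        model = make_model(codebook, 3, 2)
        assert quantization_error(model, codebook) == 0.0

    def test_single_sample_distance(self):
        model = make_model(np.zeros((2, 2)), 2, 1)
        assert quantization_error(model, np.array([[3.0, 4.0]])) == pytest.approx(5.0)

    def test_matches_brute_force_mean(self, rng):
        codebook = rng.normal(size=(9, 4))
        model = make_model(codebook, 3, 3)
        data = rng.normal(size=(30, 4))
        expected = np.mean(
            [min(np.linalg.norm(x - c) for c in codebook) for x in data]
        )
        assert quantization_error(model, data) == pytest.approx(expected)

    def test_empty_data_rejected(self, rng):
        model = make_model(rng.normal(size=(4, 2)), 2, 2)
        with pytest.raises(ValueError, match="non-empty"):
            quantization_error(model, np.empty((0, 2)))


class TestUMatrix:
    def test_constant_codebook_all_zero(self):
        model = make_model(np.ones((9, 3)), 3, 3)
        np.testing.assert_array_equal(u_matrix(model), np.zeros((3, 3)))

    def test_two_cell_grid_distance(self):
        model = make_model(np.array([[0.0, 0.0], [3.0, 4.0]]), 2, 1)
        np.testing.assert_allclose(u_matrix(model), [[5.0, 5.0]])

    def test_matches_brute_force_neighbor_average(self, rng):
        codebook = rng.normal(size=(16, 3))
        model = make_model(codebook, 4, 4)
        grid = codebook.reshape(4, 4, 3)
        result = u_matrix(model)
        for r in range(4):
            for c in range(4):
                neigh = [
                    np.linalg.norm(grid[r, c] - grid[rr, cc])
                    for rr in range(max(0, r - 1), min(4, r + 2))
                    for cc in range(max(0, c - 1), min(4, c + 2))
                    if (rr, cc) != (r, c)
                ]
                assert result[r, c] == pytest.approx(np.mean(neigh))
        assert (result >= 0).all()
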