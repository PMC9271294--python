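"""From-scratch Kohonen self-organizing map.

A SOM is a rectangular grid of cells, each storing a codebook vector in
feature space.  Online training presents one (z-scored) sample at a time:
the best-matching unit (BMU) is the cell whose codebook vector is nearest in
Euclidean distance, and every cell is pulled toward the sample with a weight
that decays as a Gaussian of its grid distance to the BMU.  The neighborhood
radius ``sigma`` and the learning rate decay asymptotically over the
presentation schedule.  Training stops when the quantization error — the
mean distance between samples and their BMUs — stops decreasing.

Features are z-scored with statistics fitted on the training data and the
scaler is stored in the model, because SOM distances are scale sensitive.
The codebook is kept in scaled space; :attr:`SOMModel.codebook_original`
gives it back in original item units.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

__all__ = ["SOMConfig", "SOMModel", "train_som", "find_bmu", "quantization_error", "u_matrix"]


@dataclass(frozen=True)
class SOMConfig:
    """Hyperparameters of the map.

    Defaults follow the configuration this package models: a 25x25 grid,
    initial neighborhood radius 1.8, initial learning rate 0.4, Gaussian
    neighborhood and Euclidean activation distance.
    """

    width: int = 25
    height: int = 25
    sigma0: float = 1.8
    learning_rate0: float = 0.4
    neighborhood: str = "gaussian"
    activation_distance: str = "euclidean"
    n_iterations_per_epoch: int | None = None  # None -> one pass worth of samples
    max_epochs: int = 100
    convergence_tol: float = 1e-4
    patience: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("width and height must be positive")
        if self.sigma0 <= 0:
            raise ValueError(f"sigma0 must be positive, got {self.sigma0}")
        if not 0 < self.learning_rate0 <= 1:
            raise ValueError(f"learning_rate0 must be in (0, 1], got {self.learning_rate0}")
        if self.neighborhood != "gaussian":
            raise ValueError(f"unsupported neighborhood {self.neighborhood!r}")
        if self.activation_distance != "euclidean":
            raise ValueError(f"unsupported activation distance {self.activation_distance!r}")
        if self.convergence_tol < 0:
            raise ValueError("convergence_tol must be non-negative")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")

    @property
    def n_cells(self) -> int:
        return self.width * self.height


@dataclass
class SOMModel:
    """A trained map: codebook (scaled space), scaler, and training log."""

    config: SOMConfig
    codebook: np.ndarray  # (n_cells, n_features), z-scored space
    feature_names: list[str]
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    training_log: list[float] = field(default_factory=list)
    initial_qe: float = float("nan")  # quantization error of the untrained codebook

    @property
    def n_cells(self) -> int:
        return self.codebook.shape[0]

    @property
    def n_features(self) -> int:
        return self.codebook.shape[1]

    @property
    def codebook_original(self) -> np.ndarray:
        """Codebook mapped back to original feature units."""
        return self.codebook * self.scaler_scale + self.scaler_mean

    def grid_coords(self, cell: int | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(row, col) of a 0-based, row-major cell index."""
        cell = np.asarray(cell)
        return cell // self.config.width, cell % self.config.width

    def cell_index(self, row: int, col: int) -> int:
        if not (0 <= row < self.config.height and 0 <= col < self.config.width):
            raise ValueError(f"cell ({row}, {col}) outside {self.config.height}x{self.config.width} grid")
        return row * self.config.width + col

    def scale(self, data: np.ndarray) -> np.ndarray:
        return (np.asarray(data, dtype=float) - self.scaler_mean) / self.scaler_scale


def _check_data(data: np.ndarray) -> np.ndarray:
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[0] < 1 or data.shape[1] < 1:
        raise ValueError(f"data must be a non-empty 2-D matrix, got shape {data.shape}")
    if not np.isfinite(data).all():
        raise ValueError("data contains non-finite values")
    return data


def _bmu_indices(codebook: np.ndarray, scaled: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised BMU lookup; ties broken toward the lowest cell index."""
    # exact differences (not the expanded quadratic form), so a sample equal
    # to a codebook vector reports distance exactly 0; argmin is tie-stable
    d = cdist(scaled, codebook)
    idx = np.argmin(d, axis=1)
    return idx, d[np.arange(len(idx)), idx]


def train_som(
    data: np.ndarray,
    config: SOMConfig,
    feature_names: Sequence[str] | None = None,
) -> SOMModel:
    """Train a SOM by sequential Kohonen updates until convergence.

    One epoch presents ``n_iterations_per_epoch`` samples (default: as many
    as there are samples) drawn with replacement.  After each epoch the
    quantization error over the full data is logged; training stops when it
    has failed to improve by more than ``convergence_tol`` for ``patience``
    consecutive epochs, or at ``max_epochs``.  The returned codebook is the
    lowest-quantization-error state encountered (initial state included), so
    the trained map is never worse than the initialization.
    """
    data = _check_data(data)
    n, p = data.shape
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(p)]
    feature_names = list(feature_names)
    if len(feature_names) != p:
        raise ValueError(
            f"feature_names has {len(feature_names)} entries for {p} features"
        )

    mean = data.mean(axis=0)
    scale = data.std(axis=0)
    scale[scale == 0] = 1.0
    scaled = (data - mean) / scale

    rng = np.random.default_rng(config.seed)
    lo, hi = scaled.min(axis=0), scaled.max(axis=0)
    codebook = rng.uniform(lo, hi, size=(config.n_cells, p))

    rows, cols = np.divmod(np.arange(config.n_cells), config.width)
    per_epoch = config.n_iterations_per_epoch or n
    total = config.max_epochs * per_epoch

    model = SOMModel(
        config=config,
        codebook=codebook,
        feature_names=feature_names,
        scaler_mean=mean,
        scaler_scale=scale,
    )

    _, d0 = _bmu_indices(codebook, scaled)
    model.initial_qe = float(d0.mean())

    # best-state restoration: the returned codebook is the lowest-QE state
    # seen (the initial codebook included), so training never degrades the
    # quantization error
    best = model.initial_qe
    best_codebook = codebook.copy()
    stall = 0
    t = 0
    for _ in range(config.max_epochs):
        sample_idx = rng.integers(0, n, size=per_epoch)
        for i in sample_idx:
            decay = 1.0 + t / (total / 2.0)
            sigma = config.sigma0 / decay
            lr = config.learning_rate0 / decay
            x = scaled[i]
            d2 = np.einsum("ij,ij->i", codebook - x, codebook - x)
            bmu = int(np.argmin(d2))
            g2 = (rows - rows[bmu]) ** 2 + (cols - cols[bmu]) ** 2
            h = lr * np.exp(-g2 / (2.0 * sigma * sigma))
            codebook += h[:, None] * (x - codebook)
            t += 1
        _, dists = _bmu_indices(codebook, scaled)
        qe = float(dists.mean())
        model.training_log.append(qe)
        if best - qe > config.convergence_tol:
            best = qe
            best_codebook = codebook.copy()
            stall = 0
        else:
            if qe < best:
                best = qe
                best_codebook = codebook.copy()
            stall += 1
            if stall >= config.patience:
                break
    model.codebook = best_codebook
    return model


def find_bmu(model: SOMModel, sample: np.ndarray) -> tuple[int, float]:
    """Best-matching unit of one sample (original units): (cell index, distance).

    The sample is z-scored with the model's stored scaler before the lookup;
    ties resolve to the lowest cell index.
    """
    sample = np.asarray(sample, dtype=float)
    if sample.shape != (model.n_features,):
        raise ValueError(
            f"sample has shape {sample.shape}, expected ({model.n_features},)"
        )
    if not np.isfinite(sample).all():
        raise ValueError("sample contains non-finite values")
    idx, dist = _bmu_indices(model.codebook, model.scale(sample)[None, :])
    return int(idx[0]), float(dist[0])


def map_samples(model: SOMModel, data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised BMU lookup for a matrix of samples in original units."""
    data = _check_data(data)
    if data.shape[1] != model.n_features:
        raise ValueError(
            f"data has {data.shape[1]} features, model expects {model.n_features}"
        )
    return _bmu_indices(model.codebook, model.scale(data))


def quantization_error(model: SOMModel, data: np.ndarray) -> float:
    """Mean Euclidean distance between samples and their BMUs (scaled space)."""
    _, dists = map_samples(model, data)
    return float(dists.mean())


def u_matrix(model: SOMModel) -> np.ndarray:
    """Mean codebook distance of each cell to its 8-connected grid neighbors.

    Returns an (height, width) array; edge and corner cells average over the
    neighbors they have.
    """
    h, w = model.config.height, model.config.width
    grid = model.codebook.reshape(h, w, model.n_features)
    out = np.zeros((h, w))
    for r in range(h):
        for c in range(w):
            dists = [
                np.linalg.norm(grid[r, c] - grid[r + dr, c + dc])
                for dr in (-1, 0, 1)
                for dc in (-1, 0, 1)
                if (dr or dc) and 0 <= r + dr < h and 0 <= c + dc < w
            ]
            out[r, c] = np.mean(dists)
    return out
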