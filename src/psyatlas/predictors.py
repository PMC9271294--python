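"""Feed-forward regressors for psychological age and future well-being.

Two regression tasks share the 32 questionnaire items as inputs: a
single-output psychological-age model and a multilabel model emitting all
six follow-up Ryff well-being scores simultaneously.  Models are evaluated
with 5-fold cross-validation on the training partition; the report carries
per-fold and pooled out-of-fold MAE, MAPE and Pearson r per target, plus
median- and mean-baseline MAE for reference.  The final model is refit on
the full training partition.

The published architecture (4 hidden layers of 256 units for age, 400 for
well-being, L2 1e-6 / 1e-7) is available through
:meth:`PredictorConfig.paper_scale`; defaults are a scaled-down 2x64
network suitable for desk-scale experiments.  The backend is a scikit-learn
``MLPRegressor`` (ReLU activation; the ``dropout_p`` field is recorded for
provenance but has no effect with this backend).

Also provided: the plain MAE / MAPE metrics, age correction that
residualises predicted age against the chronological-age trend of the
training split, and the share-of-high-scorers well-being trend curves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import pearsonr
from sklearn.model_selection import KFold
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .cohort import item_columns, wb2_columns

__all__ = [
    "PredictorConfig",
    "EvalReport",
    "train_predictor",
    "predict",
    "mae",
    "mape",
    "AgeCorrector",
    "age_correct",
    "high_scorer_fraction",
    "wellbeing_trend",
]


@dataclass(frozen=True)
class PredictorConfig:
    """Architecture and training settings for one regression task."""

    task: str = "age"  # "age" (1 output) or "wellbeing6" (6 outputs)
    hidden_layers: int = 2
    hidden_units: int = 64
    activation: str = "relu"
    dropout_p: float = 0.25  # recorded; inert under the sklearn backend
    l2_coefficient: float = 1e-6
    loss: str = "mae"
    cv_folds: int = 5
    epochs: int = 300
    batch_size: int = 32
    solver: str = "adam"  # "lbfgs" converges tighter on small noiseless fits
    seed: int = 0

    def __post_init__(self) -> None:
        if self.task not in ("age", "wellbeing6"):
            raise ValueError(f"unknown task {self.task!r}")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")

    @classmethod
    def paper_scale(cls, task: str, **kw) -> "PredictorConfig":
        """The full published architecture for a task."""
        if task == "age":
            return cls(task="age", hidden_layers=4, hidden_units=256,
                       l2_coefficient=1e-6, **kw)
        return cls(task="wellbeing6", hidden_layers=4, hidden_units=400,
                   l2_coefficient=1e-7, **kw)


@dataclass
class EvalReport:
    """Cross-validated out-of-fold metrics, one column per target."""

    targets: list[str]
    fold_mae: np.ndarray  # (folds, targets)
    fold_mape: np.ndarray
    fold_pearson: np.ndarray
    pooled_mae: np.ndarray  # (targets,)
    pooled_mape: np.ndarray
    pooled_pearson: np.ndarray
    baseline_median_mae: np.ndarray
    baseline_mean_mae: np.ndarray
    oof_predictions: pd.DataFrame = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mae": self.pooled_mae,
                "mape": self.pooled_mape,
                "pearson_r": self.pooled_pearson,
                "baseline_median_mae": self.baseline_median_mae,
                "baseline_mean_mae": self.baseline_mean_mae,
            },
            index=pd.Index(self.targets, name="target"),
        )


def mae(true: Sequence[float], predicted: Sequence[float]) -> float:
    """Mean absolute error, (1/N) * sum |true_i - predicted_i|."""
    t = np.asarray(true, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if t.shape != p.shape:
        raise ValueError(f"length mismatch: {t.shape} vs {p.shape}")
    if t.size == 0:
        raise ValueError("empty input")
    return float(np.mean(np.abs(t - p)))


def mape(true: Sequence[float], predicted: Sequence[float]) -> float:
    """Mean absolute percentage error, (100/N) * sum |true_i - predicted_i| / true_i."""
    t = np.asarray(true, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if t.shape != p.shape:
        raise ValueError(f"length mismatch: {t.shape} vs {p.shape}")
    if t.size == 0:
        raise ValueError("empty input")
    zeros = np.flatnonzero(t == 0)
    if zeros.size:
        raise ValueError(f"true value is zero at index {zeros[0]}; MAPE undefined")
    return float(100.0 * np.mean(np.abs(t - p) / np.abs(t)))


def _build_mlp(config: PredictorConfig, seed: int) -> Pipeline:
    kwargs = dict(
        hidden_layer_sizes=(config.hidden_units,) * config.hidden_layers,
        activation=config.activation,
        alpha=config.l2_coefficient,
        max_iter=config.epochs,
        solver=config.solver,
        random_state=seed,
    )
    if config.solver == "adam":
        kwargs.update(
            batch_size=config.batch_size,
            early_stopping=True,
            n_iter_no_change=10,
            validation_fraction=0.1,
        )
    net = MLPRegressor(**kwargs)
    return Pipeline([("scale", StandardScaler()), ("net", net)])


def _targets_for(config: PredictorConfig) -> list[str]:
    return ["age"] if config.task == "age" else wb2_columns()


def train_predictor(
    cohort: pd.DataFrame, config: PredictorConfig
) -> tuple[Pipeline, EvalReport]:
    """Cross-validate and fit a predictor on the training partition.

    Out-of-fold predictions over the whole training split are pooled into
    the report's metrics; the returned model is refit on all training rows.
    Deterministic for a fixed config (seed included).
    """
    train = cohort[cohort["split"] == "train"] if "split" in cohort.columns else cohort
    if len(train) == 0:
        raise ValueError("training split is empty")
    feat_cols = item_columns()
    missing = [c for c in feat_cols if c not in train.columns]
    if missing:
        raise ValueError(f"cohort lacks item columns: {missing}")
    targets = _targets_for(config)
    X = train[feat_cols].to_numpy(dtype=float)
    y = train[targets].to_numpy(dtype=float)
    if len(train) < config.cv_folds:
        raise ValueError(
            f"{len(train)} samples is fewer than cv_folds={config.cv_folds}"
        )

    kf = KFold(n_splits=config.cv_folds, shuffle=True, random_state=config.seed)
    oof = np.full_like(y, np.nan)
    fold_mae, fold_mape, fold_r = [], [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence warnings on tiny fixtures
        for f, (tr, va) in enumerate(kf.split(X)):
            model = _build_mlp(config, seed=config.seed + f + 1)
            model.fit(X[tr], y[tr].squeeze())
            pred = np.atleast_2d(model.predict(X[va]))
            if pred.shape[0] == 1 and y.shape[1] == 1:
                pred = pred.T
            elif pred.shape != y[va].shape:
                pred = pred.reshape(y[va].shape)
            oof[va] = pred
            fold_mae.append([mae(y[va, j], pred[:, j]) for j in range(y.shape[1])])
            fold_mape.append([mape(y[va, j], pred[:, j]) for j in range(y.shape[1])])
            fold_r.append(
                [
                    pearsonr(y[va, j], pred[:, j]).statistic
                    if np.std(pred[:, j]) > 0 and np.std(y[va, j]) > 0
                    else np.nan
                    for j in range(y.shape[1])
                ]
            )
        final = _build_mlp(config, seed=config.seed)
        final.fit(X, y.squeeze())

    report = EvalReport(
        targets=targets,
        fold_mae=np.asarray(fold_mae),
        fold_mape=np.asarray(fold_mape),
        fold_pearson=np.asarray(fold_r),
        pooled_mae=np.array([mae(y[:, j], oof[:, j]) for j in range(y.shape[1])]),
        pooled_mape=np.array([mape(y[:, j], oof[:, j]) for j in range(y.shape[1])]),
        pooled_pearson=np.array(
            [
                pearsonr(y[:, j], oof[:, j]).statistic
                if np.std(oof[:, j]) > 0 and np.std(y[:, j]) > 0
                else np.nan
                for j in range(y.shape[1])
            ]
        ),
        baseline_median_mae=np.array(
            [mae(y[:, j], np.full(len(y), np.median(y[:, j]))) for j in range(y.shape[1])]
        ),
        baseline_mean_mae=np.array(
            [mae(y[:, j], np.full(len(y), np.mean(y[:, j]))) for j in range(y.shape[1])]
        ),
        oof_predictions=pd.DataFrame(oof, columns=targets, index=train.index),
    )
    return final, report


def predict(model: Pipeline, cohort: pd.DataFrame, config: PredictorConfig) -> pd.DataFrame:
    """Predictions for every row of a cohort, columns named per target."""
    X = cohort[item_columns()].to_numpy(dtype=float)
    pred = np.atleast_2d(model.predict(X))
    targets = _targets_for(config)
    if pred.shape[0] == 1 and len(targets) == 1:
        pred = pred.T
    elif pred.shape != (len(cohort), len(targets)):
        pred = pred.reshape(len(cohort), len(targets))
    return pd.DataFrame(pred, columns=targets, index=cohort.index)


@dataclass
class AgeCorrector:
    """Linear fit of predicted age on chronological age (training split only).

    Correction replaces the cohort-level age trend of the raw prediction:
    corrected = chronological + (predicted - E[predicted | chronological]).
    Within the training data the corrected ages deviate from chronological
    age by (near-)zero on average, so the corrected value reads as
    "psychologically older/younger than one's age peers".
    """

    slope: float
    intercept: float

    @classmethod
    def fit(cls, predicted: np.ndarray, chronological: np.ndarray) -> "AgeCorrector":
        chron = np.asarray(chronological, dtype=float)
        pred = np.asarray(predicted, dtype=float)
        if np.std(chron) == 0:
            raise ValueError("chronological age is constant; correction fit is degenerate")
        slope, intercept = np.polyfit(chron, pred, deg=1)
        return cls(slope=float(slope), intercept=float(intercept))

    def __call__(self, predicted: np.ndarray, chronological: np.ndarray) -> np.ndarray:
        pred = np.asarray(predicted, dtype=float)
        chron = np.asarray(chronological, dtype=float)
        expected = self.slope * chron + self.intercept
        return chron + (pred - expected)


def age_correct(
    predicted_age: np.ndarray,
    chronological_age: np.ndarray,
    reference_fit: AgeCorrector,
) -> np.ndarray:
    """Apply a training-split age-correction fit to new predictions."""
    return reference_fit(predicted_age, chronological_age)


def high_scorer_fraction(
    ages: np.ndarray,
    scores: np.ndarray,
    scale_max: float,
    age_bins: np.ndarray,
) -> pd.Series:
    """Per age-bin fraction of subjects scoring >= 90% of the scale maximum.

    Bins are [edge_i, edge_{i+1}) half-open (last bin closed); empty bins
    yield NaN.  The right-skew of well-being scores makes this share a more
    faithful trend statistic than bin means or medians.
    """
    ages = np.asarray(ages, dtype=float)
    scores = np.asarray(scores, dtype=float)
    age_bins = np.asarray(age_bins, dtype=float)
    if ages.min() < age_bins[0] or ages.max() > age_bins[-1]:
        raise ValueError(
            f"age bins [{age_bins[0]}, {age_bins[-1]}] do not cover observed ages "
            f"[{ages.min():.1f}, {ages.max():.1f}]"
        )
    idx = np.clip(np.digitize(ages, age_bins) - 1, 0, len(age_bins) - 2)
    high = scores >= 0.9 * scale_max
    frac = np.full(len(age_bins) - 1, np.nan)
    for b in range(len(age_bins) - 1):
        mask = idx == b
        if mask.any():
            frac[b] = high[mask].mean()
    labels = [f"[{age_bins[b]:g},{age_bins[b + 1]:g})" for b in range(len(age_bins) - 1)]
    return pd.Series(frac, index=pd.Index(labels, name="age_bin"), name="fraction_high")


def wellbeing_trend(
    ages: np.ndarray,
    actual_scores: np.ndarray,
    predicted_scores: np.ndarray,
    scale_max: float,
    age_bins: np.ndarray | None = None,
    bin_width: float = 5.0,
) -> tuple[pd.DataFrame, float]:
    """Actual vs predicted high-scorer trend curves and their MAPE.

    Returns the two per-bin fraction curves and the MAPE between them over
    bins where both are defined and the actual fraction is nonzero; other
    bins are excluded with a warning.
    """
    ages = np.asarray(ages, dtype=float)
    if age_bins is None:
        lo = np.floor(ages.min() / bin_width) * bin_width
        hi = np.ceil(ages.max() / bin_width) * bin_width
        if hi <= lo:
            hi = lo + bin_width
        age_bins = np.arange(lo, hi + bin_width / 2, bin_width)
    actual = high_scorer_fraction(ages, actual_scores, scale_max, age_bins)
    predicted = high_scorer_fraction(ages, predicted_scores, scale_max, age_bins)
    curves = pd.DataFrame({"actual": actual, "predicted": predicted})
    usable = np.isfinite(actual) & np.isfinite(predicted) & (actual != 0)
    dropped = [str(b) for b in curves.index[~usable]]
    if dropped:
        warnings.warn(
            f"excluding {len(dropped)} bin(s) with no subjects or zero actual "
            f"fraction from trend MAPE: {dropped}",
            stacklevel=2,
        )
    if not usable.any():
        return curves, float("nan")
    trend_mape = mape(actual[usable.to_numpy()], predicted[usable.to_numpy()])
    return curves, trend_mape
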