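"""Feature relevance, collinearity filtering, and relative importance.

Three stages mirror a feature-selection-and-importance workflow for
questionnaire predictors of future well-being:

* :func:`shadow_select` — Boruta-style all-relevant selection.  Each round
  appends a permuted ("shadow") copy of every feature, fits a random-forest
  importance model, and counts a hit for every real feature whose importance
  beats the best shadow.  A binomial test over rounds confirms features that
  hit significantly more often than chance and rejects the converse; the
  rest stay tentative.  With several targets, decisions are the union of
  per-target confirmations.
* :func:`vif_filter` — iterative variance-inflation-factor screen: the
  feature with the highest VIF is removed (highest first, index tie-break)
  until all remaining VIFs are at or below the threshold (10 by default).
* :func:`en_importance` — elastic-net relative importance of sex, age, the
  model-predicted future well-being, and the six baseline well-being scores
  for one follow-up well-being dimension.  Hyperparameters are chosen by
  5-fold cross-validated MAE over the fixed grid: l1_ratio 0..1 in steps of
  0.01 and penalty weights {1e-5, 1e-4, 1e-3, 1e-2, 1e-1, 0.0, 1.0, 10,
  100}; a penalty of 0.0 is the unpenalised least-squares limit.
  Predictors are standardized before fitting so coefficient magnitudes are
  comparable; the winner is the predictor with the largest |coefficient|.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binomtest
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import ElasticNet, LinearRegression
from sklearn.model_selection import KFold
from statsmodels.stats.outliers_influence import variance_inflation_factor

from .cohort import wb1_columns

__all__ = [
    "SelectionReport",
    "ImportanceEntry",
    "shadow_select",
    "vif_filter",
    "en_importance",
    "EN_L1_RATIOS",
    "EN_PENALTIES",
]

#: Fixed elastic-net search grid.
EN_L1_RATIOS = np.round(np.arange(0.0, 1.0 + 1e-9, 0.01), 2)
EN_PENALTIES = (1e-5, 1e-4, 1e-3, 1e-2, 1e-1, 0.0, 1.0, 10.0, 100.0)


@dataclass
class SelectionReport:
    """Outcome of shadow-feature selection (optionally + VIF filtering)."""

    decisions: pd.Series  # feature -> {"confirmed", "rejected", "tentative"}
    hit_counts: pd.DataFrame  # features x targets
    n_rounds: int
    alpha: float
    vif: pd.Series | None = None
    final_features: list[str] = field(default_factory=list)

    @property
    def confirmed(self) -> list[str]:
        return list(self.decisions.index[self.decisions == "confirmed"])

    @property
    def rejected(self) -> list[str]:
        return list(self.decisions.index[self.decisions == "rejected"])


def shadow_select(
    features: pd.DataFrame,
    target: np.ndarray | pd.DataFrame,
    n_rounds: int = 50,
    alpha: float = 0.01,
    n_estimators: int = 80,
    seed: int = 0,
) -> SelectionReport:
    """Boruta-style all-relevant feature selection against shadow features.

    ``target`` may be one column or a matrix of columns (e.g. the six
    follow-up well-being scores); with several targets each is screened
    separately and a feature confirmed for any target is confirmed overall,
    while rejection must be unanimous.
    """
    X = pd.DataFrame(features)
    if X.shape[1] < 2:
        raise ValueError("need at least 2 features")
    if n_rounds < 10:
        raise ValueError("n_rounds must be >= 10 for the binomial test to resolve")
    Y = np.asarray(target, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    target_names = (
        list(target.columns)
        if isinstance(target, pd.DataFrame)
        else [f"target_{j}" for j in range(Y.shape[1])]
    )
    for j in range(Y.shape[1]):
        if np.std(Y[:, j]) == 0:
            raise ValueError(f"target {target_names[j]!r} is constant")

    rng = np.random.default_rng(seed)
    n, p = X.shape
    Xv = X.to_numpy(dtype=float)
    hits = np.zeros((p, Y.shape[1]), dtype=int)
    for r in range(n_rounds):
        perm = rng.permuted(Xv, axis=0)
        design = np.hstack([Xv, perm])
        for j in range(Y.shape[1]):
            forest = RandomForestRegressor(
                n_estimators=n_estimators,
                max_features="sqrt",
                random_state=int(rng.integers(0, 2**31 - 1)),
                n_jobs=1,
            )
            forest.fit(design, Y[:, j])
            imp = forest.feature_importances_
            hits[:, j] += imp[:p] > imp[p:].max()

    decisions = []
    for i in range(p):
        per_target = []
        for j in range(Y.shape[1]):
            k = int(hits[i, j])
            if binomtest(k, n_rounds, 0.5, alternative="greater").pvalue < alpha:
                per_target.append("confirmed")
            elif binomtest(k, n_rounds, 0.5, alternative="less").pvalue < alpha:
                per_target.append("rejected")
            else:
                per_target.append("tentative")
        if "confirmed" in per_target:
            decisions.append("confirmed")
        elif all(d == "rejected" for d in per_target):
            decisions.append("rejected")
        else:
            decisions.append("tentative")

    report = SelectionReport(
        decisions=pd.Series(decisions, index=X.columns, name="decision"),
        hit_counts=pd.DataFrame(hits, index=X.columns, columns=target_names),
        n_rounds=n_rounds,
        alpha=alpha,
    )
    report.final_features = report.confirmed
    return report


def vif_filter(
    features: pd.DataFrame, threshold: float = 10.0
) -> tuple[list[str], pd.Series]:
    """Iteratively drop the highest-VIF feature until all VIFs <= threshold.

    VIF_j = 1/(1-R^2_j) from regressing feature j on all others.  Infinite
    VIFs (perfect collinearity) are removed first; ties resolve to the
    lowest column index.  Returns (surviving features, their final VIFs).
    """
    X = pd.DataFrame(features)
    if X.shape[1] < 2:
        raise ValueError("need at least 2 features")
    const = [c for c in X.columns if X[c].nunique() <= 1]
    if const:
        raise ValueError(f"constant columns not allowed: {const}")

    cols = list(X.columns)
    while True:
        # statsmodels assumes the design carries a constant; prepend one and
        # report VIFs for the real features only
        M = np.column_stack([np.ones(len(X)), X[cols].to_numpy(dtype=float)])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # statsmodels divide-by-zero on exact collinearity
            vifs = np.array(
                [variance_inflation_factor(M, i + 1) for i in range(len(cols))]
            )
        if len(cols) == 2 or np.nanmax(vifs) <= threshold:
            break
        worst = int(np.argmax(np.where(np.isnan(vifs), np.inf, vifs)))
        cols.pop(worst)
    return cols, pd.Series(vifs, index=cols, name="vif")


@dataclass
class ImportanceEntry:
    """Relative-importance result for one well-being dimension."""

    dimension: str
    coefficients: pd.Series  # standardized-predictor coefficients
    l1_ratio: float
    penalty: float
    cv_mae: float
    winner: str
    tie: bool


def _cv_mae_en(X: np.ndarray, y: np.ndarray, penalty: float, l1_ratio: float,
               splits: list[tuple[np.ndarray, np.ndarray]]) -> float:
    errs = []
    for tr, va in splits:
        model = _en_model(penalty, l1_ratio)
        model.fit(X[tr], y[tr])
        errs.append(np.mean(np.abs(y[va] - model.predict(X[va]))))
    return float(np.mean(errs))


def _en_model(penalty: float, l1_ratio: float):
    if penalty == 0.0:
        return LinearRegression()
    return ElasticNet(alpha=penalty, l1_ratio=l1_ratio, max_iter=5000)


def en_importance(
    cohort: pd.DataFrame,
    predicted_wb: pd.Series | np.ndarray,
    dimension: int,
    cv_folds: int = 5,
    seed: int = 0,
) -> ImportanceEntry:
    """Elastic-net relative importance for one follow-up well-being dimension.

    ``dimension`` is 0-based (0..5).  The design matrix holds sex (male=1),
    age, the predicted future well-being for that dimension, and the six
    baseline well-being scores; all predictors are standardized and the
    grid-search winner is refit on the full data.
    """
    if not 0 <= dimension <= 5:
        raise ValueError("dimension must be in 0..5")
    predicted = np.asarray(predicted_wb, dtype=float)
    if predicted.shape != (len(cohort),):
        raise ValueError("predicted_wb must have one value per cohort row")
    if np.isnan(predicted).any():
        raise ValueError("predicted_wb contains missing values")
    target_col = f"wb2_{dimension + 1}"
    if target_col not in cohort.columns:
        raise ValueError(f"cohort lacks follow-up column {target_col}")

    design = pd.DataFrame(
        {
            "sex": (np.asarray(cohort["sex"]) == "male").astype(float),
            "age": cohort["age"].to_numpy(dtype=float),
            "predicted_wb": predicted,
            **{c: cohort[c].to_numpy(dtype=float) for c in wb1_columns()},
        }
    )
    X = design.to_numpy()
    X = (X - X.mean(axis=0)) / X.std(axis=0)
    y = cohort[target_col].to_numpy(dtype=float)

    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    splits = list(kf.split(X))
    best = (np.inf, None, None)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # EN convergence chatter on extreme grid corners
        for penalty in EN_PENALTIES:
            ratios = [0.0] if penalty == 0.0 else EN_L1_RATIOS
            for l1 in ratios:
                err = _cv_mae_en(X, y, penalty, l1, splits)
                if err < best[0]:
                    best = (err, penalty, l1)
        cv_mae, penalty, l1_ratio = best
        final = _en_model(penalty, l1_ratio)
        final.fit(X, y)

    coefs = pd.Series(np.ravel(final.coef_), index=design.columns, name="coefficient")
    order = coefs.abs().sort_values(ascending=False)
    winner = str(order.index[0])
    tie = len(order) > 1 and np.isclose(order.iloc[0], order.iloc[1])
    return ImportanceEntry(
        dimension=target_col,
        coefficients=coefs,
        l1_ratio=float(l1_ratio),
        penalty=float(penalty),
        cv_mae=float(cv_mae),
        winner=winner,
        tie=tie,
    )
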