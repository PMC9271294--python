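"""Seeded synthetic cohorts with the structure of a midlife questionnaire panel.

The generator emulates a two-wave survey cohort: 32 bounded Likert-type
attitude items, chronological age, sex, six baseline (wave-1) and six
follow-up (wave-2) psychological well-being scores on the Ryff dimensions,
and a binary depression label.  Planted structure makes every downstream
stage testable without access to restricted survey data:

* the depressed subpopulation is shifted in item space by a configurable
  per-item mean-shift vector;
* follow-up well-being is a smooth nonlinear (sigmoidal) function of the
  items plus Gaussian noise, then clipped to the score scale;
* baseline well-being is right-skewed (scaled Beta) and weakly aligned with
  the item signal;
* a subset of items drifts linearly with age, so age is recoverable from
  the questionnaire and the well-being/age trend curves are non-flat.

The default cohort proportions follow the study design this package models:
a training partition of 2718 subjects containing no depressed individuals,
and a test partition of 394 depressed plus 779 non-depressed subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import truncnorm

__all__ = [
    "CohortSpec",
    "generate_cohort",
    "item_columns",
    "wb1_columns",
    "wb2_columns",
    "COHORT_COLUMNS",
    "default_depression_shift",
    "default_wellbeing_link",
]

N_ITEMS_DEFAULT = 32
N_WB = 6

#: Ryff psychological well-being dimensions, in fixed order.
WB_DIMENSIONS = (
    "autonomy",
    "environmental_mastery",
    "personal_growth",
    "positive_relations",
    "purpose_in_life",
    "self_acceptance",
)


def item_columns(n_items: int = N_ITEMS_DEFAULT) -> list[str]:
    return [f"item_{i + 1:02d}" for i in range(n_items)]


def wb1_columns() -> list[str]:
    return [f"wb1_{i + 1}" for i in range(N_WB)]


def wb2_columns() -> list[str]:
    return [f"wb2_{i + 1}" for i in range(N_WB)]


#: Fixed cohort CSV header (32-item default).
COHORT_COLUMNS = (
    ["subject_id"]
    + item_columns()
    + ["age", "sex"]
    + wb1_columns()
    + wb2_columns()
    + ["depressed", "split"]
)


def default_depression_shift(n_items: int = N_ITEMS_DEFAULT) -> np.ndarray:
    """Per-item mean shift of the depressed subpopulation.

    Depressed respondents score one point lower on the first eight items
    (adaptive, coping-style attitudes) and one point higher on the next
    eight (distress-style attitudes); the remaining items are unshifted.
    """
    shift = np.zeros(n_items)
    shift[: min(8, n_items)] = -1.0
    if n_items > 8:
        shift[8 : min(16, n_items)] = 1.0
    return shift


def default_wellbeing_link(n_items: int = N_ITEMS_DEFAULT) -> np.ndarray:
    """Coefficients of the planted items -> follow-up well-being mapping.

    Rows are the six well-being dimensions, columns the items.  The first
    eight items load positively and the next eight negatively (so the
    depression shift lowers every planted well-being dimension), and each
    dimension puts a small distinct weight on one of the age-drifting items
    so the six dimensions are not interchangeable.
    """
    coef = np.zeros((N_WB, n_items))
    coef[:, : min(8, n_items)] = 0.5
    if n_items > 8:
        coef[:, 8 : min(16, n_items)] = -0.5
    for d in range(N_WB):
        if 16 + d < n_items:
            coef[d, 16 + d] = -0.4 if d in (2, 4) else 0.4
    return coef


@dataclass
class CohortSpec:
    """Parameters of a synthetic two-wave cohort.

    Defaults reproduce the modelled study conditions: 2718 training subjects
    (all non-depressed) and a 1173-subject test partition with 394 depressed
    and 779 non-depressed respondents, 32 items on a 1-7 Likert scale.
    """

    n_train: int = 2718
    n_test_depressed: int = 394
    n_test_nondepressed: int = 779
    n_items: int = N_ITEMS_DEFAULT
    item_scale: Tuple[float, float] = (1.0, 7.0)
    wb_scale: Tuple[float, float] = (1.0, 7.0)
    depression_shift: np.ndarray | None = None
    wellbeing_link: np.ndarray | None = None
    noise_sd: float = 0.5
    seed: int = 0
    # secondary shape parameters (see docs/methods.md)
    item_sd: float = 1.1
    trait_sd: float = 2.0
    secondary_trait_sd: float = 1.0
    age_range: Tuple[float, float] = (25.0, 74.0)
    age_slope: float = 0.8
    baseline_item_weight: float = 0.3
    p_male_depressed: float = 0.32
    p_male_nondepressed: float = 0.41

    def __post_init__(self) -> None:
        for name in ("n_train", "n_test_depressed", "n_test_nondepressed", "n_items"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        lo, hi = self.item_scale
        if not lo < hi:
            raise ValueError(f"item_scale must satisfy min < max, got {self.item_scale}")
        lo, hi = self.wb_scale
        if not lo < hi:
            raise ValueError(f"wb_scale must satisfy min < max, got {self.wb_scale}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be non-negative, got {self.noise_sd}")
        if self.depression_shift is None:
            self.depression_shift = default_depression_shift(self.n_items)
        self.depression_shift = np.asarray(self.depression_shift, dtype=float)
        if self.depression_shift.shape != (self.n_items,):
            raise ValueError(
                f"depression_shift must have length n_items={self.n_items}, "
                f"got shape {self.depression_shift.shape}"
            )
        if self.wellbeing_link is None:
            self.wellbeing_link = default_wellbeing_link(self.n_items)
        self.wellbeing_link = np.asarray(self.wellbeing_link, dtype=float)
        if self.wellbeing_link.shape != (N_WB, self.n_items):
            raise ValueError(
                f"wellbeing_link must have shape (6, {self.n_items}), "
                f"got {self.wellbeing_link.shape}"
            )


def _trait_patterns(spec: CohortSpec) -> tuple[np.ndarray, np.ndarray]:
    """Item loadings of the two latent attitude traits.

    Items correlate through latent traits rather than varying independently,
    which is what gives the 2-D map axes to represent.  The primary "coping"
    trait points along the normalized depression-shift direction (so the
    depressed subpopulation is displaced along a direction the map embeds);
    the secondary trait is an orthogonal alternating pattern over the same
    items.
    """
    norm = np.linalg.norm(spec.depression_shift)
    primary = spec.depression_shift / norm if norm > 0 else np.zeros(spec.n_items)
    secondary = np.zeros(spec.n_items)
    k = min(16, spec.n_items)
    secondary[:k] = np.where(np.arange(k) % 2 == 0, 1.0, -1.0)
    s_norm = np.linalg.norm(secondary)
    if s_norm > 0:
        # project out the primary direction, keep unit length
        secondary -= secondary @ primary * primary
        s_norm = np.linalg.norm(secondary)
        secondary = secondary / s_norm if s_norm > 0 else secondary
    return primary, secondary


def _age_slopes(spec: CohortSpec) -> np.ndarray:
    """Items 17-24 drift upward with age, items 25-32 downward."""
    slopes = np.zeros(spec.n_items)
    if spec.n_items > 16:
        slopes[16 : min(24, spec.n_items)] = spec.age_slope
    if spec.n_items > 24:
        slopes[24 : min(32, spec.n_items)] = -spec.age_slope
    return slopes


def planted_wb2(items: np.ndarray, spec: CohortSpec) -> np.ndarray:
    """Noise-free planted follow-up well-being, shape (n, 6).

    Each dimension is a sigmoid of a normalised linear combination of the
    centred items, rescaled to the well-being score range.  Monotone in the
    item signal but nonlinear, so linear baselines underfit it while a small
    feed-forward network recovers it.
    """
    lo, hi = spec.wb_scale
    mid = 0.5 * (spec.item_scale[0] + spec.item_scale[1])
    centred = items - mid
    out = np.empty((items.shape[0], N_WB))
    for d in range(N_WB):
        coef = spec.wellbeing_link[d]
        norm = np.linalg.norm(coef)
        u = centred @ coef / norm if norm > 0 else np.zeros(items.shape[0])
        out[:, d] = lo + (hi - lo) * expit(u)
    return out


def _truncnorm_items(rng: np.random.Generator, means: np.ndarray, spec: CohortSpec) -> np.ndarray:
    lo, hi = spec.item_scale
    sd = spec.item_sd
    a = (lo - means) / sd
    b = (hi - means) / sd
    return truncnorm.rvs(a, b, loc=means, scale=sd, random_state=rng)


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Generate a synthetic cohort table.

    Returns a DataFrame with the fixed cohort schema (``COHORT_COLUMNS`` for
    32 items): one row per subject, no missing values, item and well-being
    scores within their declared scales, zero depressed subjects in the
    training partition, and bit-identical output for identical specs.
    """
    root = np.random.SeedSequence(spec.seed)
    rng_age, rng_sex, rng_traits, rng_items, rng_wb1, rng_wb2 = (
        np.random.default_rng(s) for s in root.spawn(6)
    )

    n_total = spec.n_train + spec.n_test_depressed + spec.n_test_nondepressed
    depressed = np.zeros(n_total, dtype=bool)
    split = np.array(["train"] * spec.n_train + ["test"] * (n_total - spec.n_train))
    depressed[spec.n_train : spec.n_train + spec.n_test_depressed] = True

    age = rng_age.uniform(*spec.age_range, size=n_total)
    a = (age - np.mean(spec.age_range)) / (0.5 * np.ptp(spec.age_range))

    p_male = np.where(depressed, spec.p_male_depressed, spec.p_male_nondepressed)
    sex = np.where(rng_sex.uniform(size=n_total) < p_male, "male", "female")

    mid = 0.5 * (spec.item_scale[0] + spec.item_scale[1])
    primary, secondary = _trait_patterns(spec)
    t1 = rng_traits.normal(0.0, spec.trait_sd, size=n_total)
    t2 = rng_traits.normal(0.0, spec.secondary_trait_sd, size=n_total)
    means = np.full((n_total, spec.n_items), mid)
    means += np.outer(t1, primary) + np.outer(t2, secondary)
    means += np.outer(a, _age_slopes(spec))
    means[depressed] += spec.depression_shift
    lo, hi = spec.item_scale
    means = np.clip(means, lo + 1e-9, hi - 1e-9)  # keep truncnorm well posed
    items = _truncnorm_items(rng_items, means, spec)

    wb_lo, wb_hi = spec.wb_scale
    wb2_clean = planted_wb2(items, spec)
    wb2 = np.clip(
        wb2_clean + rng_wb2.normal(0.0, spec.noise_sd, size=wb2_clean.shape),
        wb_lo,
        wb_hi,
    )

    # right-skewed baseline scores, weakly aligned with the item signal
    base = wb_lo + (wb_hi - wb_lo) * rng_wb1.beta(5.0, 1.5, size=(n_total, N_WB))
    wb1 = np.clip(
        base + spec.baseline_item_weight * (wb2_clean - wb2_clean.mean(axis=0)),
        wb_lo,
        wb_hi,
    )

    table = pd.DataFrame(
        {
            "subject_id": np.arange(n_total),
            **{c: items[:, i] for i, c in enumerate(item_columns(spec.n_items))},
            "age": age,
            "sex": sex,
            **{c: wb1[:, i] for i, c in enumerate(wb1_columns())},
            **{c: wb2[:, i] for i, c in enumerate(wb2_columns())},
            "depressed": depressed,
            "split": split,
        }
    )
    return table
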