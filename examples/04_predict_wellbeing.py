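"""Cross-validated predictors of psychological age and future well-being.

Both models read the 32 questionnaire items.  The age model's raw output is
then residualised against the chronological-age trend ("how old does this
psyche look relative to age peers"), and the well-being model's predictions
are compared to the actual scores through the share-of-high-scorers trend
curve, the statistic of choice for right-skewed scores.
"""

import numpy as np

from psyatlas import (
    AgeCorrector,
    CohortSpec,
    PredictorConfig,
    generate_cohort,
    train_predictor,
    wellbeing_trend,
)
from psyatlas.predictors import predict

cohort = generate_cohort(CohortSpec(seed=1))
train = cohort[cohort["split"] == "train"]
test = cohort[cohort["split"] == "test"]

age_model, age_report = train_predictor(cohort, PredictorConfig(task="age", seed=1))
print("psychological age (5-fold out-of-fold):")
print(age_report.to_frame().round(2).to_string())

pred_train = predict(age_model, train, PredictorConfig(task="age"))["age"]
corrector = AgeCorrector.fit(pred_train.to_numpy(), train["age"].to_numpy())
pred_test = predict(age_model, test, PredictorConfig(task="age"))["age"]
corrected = corrector(pred_test.to_numpy(), test["age"].to_numpy())
print(f"\nafter age correction the mean deviation from chronological age is "
      f"{np.mean(corrected - test['age']):.2f} years (raw bias removed; "
      f"residual = psychological offset from age peers)")

wb_model, wb_report = train_predictor(cohort, PredictorConfig(task="wellbeing6", seed=1))
print("\nfuture well-being, six Ryff dimensions (out-of-fold):")
print(wb_report.to_frame().round(2).to_string())

preds = predict(wb_model, test, PredictorConfig(task="wellbeing6"))
curves, trend_mape = wellbeing_trend(
    test["age"].to_numpy(), test["wb2_1"].to_numpy(), preds["wb2_1"].to_numpy(),
    scale_max=7.0,
)
print("\nshare of subjects at >= 90% of the scale maximum, by 5-year age bin "
      "(dimension 1):")
print(curves.round(3).to_string())
print(f"trend MAPE between predicted and actual curves: {trend_mape:.1f}%")
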