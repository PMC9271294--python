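"""Generate a synthetic two-wave questionnaire cohort and inspect it.

The generator plants the structure every later stage relies on: a depressed
subpopulation shifted in item space, right-skewed well-being scores, and
follow-up well-being that is a nonlinear function of the items.
"""

import numpy as np

from psyatlas import CohortSpec, generate_cohort
from psyatlas.cohort import item_columns, wb1_columns

spec = CohortSpec(seed=1)  # study conditions: 2718 train, 394+779 test
cohort = generate_cohort(spec)

print(cohort["split"].value_counts().to_string())
print("depressed in train:", int(cohort.query("split=='train'")["depressed"].sum()))
print("depressed in test: ", int(cohort.query("split=='test'")["depressed"].sum()))

test = cohort[cohort["split"] == "test"]
delta = (
    test[test["depressed"]][item_columns()].mean()
    - test[~test["depressed"]][item_columns()].mean()
)
print("\nlargest item-mean shifts of the depressed subpopulation:")
print(delta.abs().nlargest(4).round(2).to_string())

wb1 = cohort[wb1_columns()].to_numpy().ravel()
print(f"\nbaseline well-being: median {np.median(wb1):.2f} on a 1-7 scale "
      f"(mass near the top: mean/median are not representative of the trend)")
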