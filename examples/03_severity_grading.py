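"""Train and evaluate the four-level tortuosity severity classifiers.

Generates a labeled synthetic dataset (100 images per grade), runs
10-fold cross-validation for the three model kinds, and grades two fresh
images with the trained random forest.
"""

import numpy as np

from vesseltort import (ClassifierConfig, cross_validate, join_labels,
                        predict_severity, train)
from vesseltort.features import GRADE_NAMES
from vesseltort.synthetic import generate_labeled_dataset

features, labels = generate_labeled_dataset(n_per_grade=100, seed=42)
labeled = join_labels(features, labels)
print(f"dataset: {len(labeled)} images, "
      f"{len(labeled.columns) - 2} features per image\n")

for kind in ("tree", "rotation_forest", "random_forest"):
    report = cross_validate(labeled, ClassifierConfig(
        model_kind=kind, n_trees=105, seed=7))
    print(f"{kind:16s} accuracy {report.accuracy:.3f}  kappa "
          f"{report.kappa:.3f}  rmse {report.rmse:.4f}  mae {report.mae:.4f}")

model = train(labeled, ClassifierConfig(model_kind="random_forest",
                                        n_trees=105, seed=7))
fresh, fresh_labels = generate_labeled_dataset(n_per_grade=1, seed=999)
grades, proba = predict_severity(model, fresh)
print("\nfresh images:")
for img, true, g, p in zip(fresh["image_id"], fresh_labels["grade"],
                           grades, proba):
    print(f"  {img}: predicted {g} ({GRADE_NAMES[int(g)]}), true {true}, "
          f"p={np.round(p, 2)}")
print("\nAccuracy near 1 and kappa near 1 mean the ordinal severity "
      "grades are fully recoverable from the image-level tortuosity "
      "features on this synthetic ladder.")
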