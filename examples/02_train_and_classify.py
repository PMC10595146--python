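"""Train the RF + SVM AND-ensemble on synthetic crops and validate it.

Generates 1,000 labelled 32x32 crops (500 olive flies / 500 others),
splits them 9:1, augments the training partition, trains both models
with the deployed hyperparameters and prints validation accuracy for
RF, SVM and the AND-ensemble.
"""

import numpy as np

from flytrap import (
    AugmentationConfig, LabelledDataset, augment_training_set,
    generate_crop_dataset, split_dataset, train_bundle,
)
from flytrap.classify import svm_dual_coefficients

crops, labels = generate_crop_dataset(500, 250, 250, seed=42)
dataset = LabelledDataset(crops=crops, labels3=labels)
train, val = split_dataset(dataset, val_fraction=0.1, seed=0)
train = augment_training_set(train, AugmentationConfig(seed=0))
print(f"training on {len(train)} crops (after augmentation), "
      f"validating on {len(val)}")

bundle = train_bundle(train)  # RF: 3 trees/depth 20; SVM: poly, C=0.1, gamma=1
votes = bundle.predict(val.crops)
y = np.asarray(val.labels2)
for name, col in (("RF", "rf_vote"), ("SVM", "svm_vote"),
                  ("RF+SVM (AND)", "ensemble")):
    acc = (votes[col].to_numpy() == y).mean()
    print(f"  {name:13s} validation accuracy {acc:.3f}")

alphas, residual = svm_dual_coefficients(bundle.svm)
print(f"SVM dual feasibility: alpha in [{alphas.min():.2e}, "
      f"{alphas.max():.2e}] (C={bundle.svm_config.C}), "
      f"sum(alpha*y)={residual:.1e}")
# The AND rule only calls an olive fly when both models agree, so its
# false-positive count can never exceed either model's.
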