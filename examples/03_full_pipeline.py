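"""Run the full inference pipeline on a synthetic trap image.

Segment the yellow panel, locate dark elements, classify each 32x32
crop with the trained bundle, and report the AND-validated fly count.
"""

import numpy as np

from flytrap import (
    LabelledDataset, SceneSpec, generate_crop_dataset, generate_trap_image,
    process_image, split_dataset, train_bundle,
)

crops, labels = generate_crop_dataset(500, 250, 250, seed=42)
train, _ = split_dataset(LabelledDataset(crops=crops, labels3=labels), seed=0)
bundle = train_bundle(train)

spec = SceneSpec(width=800, height=600, n_olive_flies=6, n_other_flies=3,
                 n_distractors=4, seed=17)
image, truth = generate_trap_image(spec)
true_flies = sum(el.label == "olive_fly" for el in truth)

report = process_image(image, bundle)
print(f"located {report['n_elements']} dark elements; "
      f"validated olive flies: {report['olive_fly_count']} "
      f"(ground truth: {true_flies})")
for det in report["detections"]:
    b = det["box"]
    mark = "OLIVE FLY" if det["olive_fly"] else "-"
    print(f"  box ({b['x']:4d},{b['y']:4d},{b['w']:3d},{b['h']:3d})  "
          f"rf={det['rf_vote']:10s} svm={det['svm_vote']:10s}  {mark}")
# An element is marked only when the RF vote AND the SVM vote agree on
# the positive class; disagreements stay unmarked.
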