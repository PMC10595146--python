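"""Two-week detection evolution: per-day TP/FP/FN for RF, SVM, ensemble.

Simulates a trap over 14 days (flies persist, new ones arrive at ~0.5/
day, lighting varies day to day), runs detection + classification each
day and prints the per-day tally against ground truth.
"""

from flytrap import (
    LabelledDataset, SceneSpec, count_series, generate_crop_dataset,
    generate_sequence, split_dataset, train_bundle,
)
from flytrap.evaluate import series_to_frame

crops, labels = generate_crop_dataset(500, 250, 250, seed=42)
train, _ = split_dataset(LabelledDataset(crops=crops, labels3=labels), seed=0)
bundle = train_bundle(train)

spec = SceneSpec(width=800, height=600, n_olive_flies=0, n_other_flies=2,
                 n_distractors=3, seed=5, distractor_kinds=("hole", "glyph"))
sequence = generate_sequence(spec, days=14, arrival_rate=0.5)

series = count_series(sequence, bundle)
frame = series_to_frame(series)
frame["date"] = frame["date"].dt.date
print(frame.pivot(index="date", columns="model",
                  values=["tp", "fp", "fn"]).to_string())
print("\ntrue olive-fly count per day:",
      [c.true_count for c in series["ensemble"]])
# tp + fn always equals the true count; the ensemble's fp column is
# bounded above by both single-model fp columns (AND rule).
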