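"""Train the desk-scale CNN on a synthetic cohort and read the metric panel.

Runs the subject-wise 8:1:1 hold-out: participants (never images) are
assigned to train/validation/test, the training composites are augmented
tenfold, and the small CNN is trained with AdaMax until validation loss
stalls. Takes a couple of minutes on one CPU.
"""

from voicescreen import (
    AugmentConfig,
    ModelSpec,
    SplitPlan,
    TrainConfig,
    holdout_evaluate,
    load_png,
    make_cohort,
    strong_effect,
)
from voicescreen.features import featurize_manifest
from voicescreen.ingest import standardize_manifest

manifest = make_cohort(16, strong_effect(), seed=11, out_dir="scratch/ex4/wav")
std = standardize_manifest(manifest.responses, "scratch/ex4/std")
index = featurize_manifest(std, "scratch/ex4/composites")
images = [load_png(p) for p in index["image_path"]]

report, history = holdout_evaluate(
    images,
    index,
    SplitPlan(mode="holdout", seed=0),
    ModelSpec(architecture="small_cnn"),
    TrainConfig(learning_rate=1e-2, max_epochs=60, seed=0),
    AugmentConfig(seed=0),
)

print(f"trained {len(history['val_loss'])} epochs "
      f"(early stop patience 3 on validation loss)")
print(f"confusion: TP={report.tp} FN={report.fn} FP={report.fp} TN={report.tn}")
for name in ("sensitivity", "specificity", "accuracy", "ppv", "npv", "f1", "auc"):
    print(f"{name:12s} {getattr(report, name):.4f}")
# Sensitivity is the fraction of AD test participants flagged; AUC is the
# probability a random AD participant scores above a random control.
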