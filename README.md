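# voicescreen

A voice-only screening pipeline for Alzheimer's disease (AD) built on the
acoustics of short spoken answers — no transcription, no semantics. During a
standard cognitive screening interview, twelve short spoken-answer items
(month orientation, three-word registration, serial subtraction, delayed
recall) are recorded; AD speech shows slow pace, hesitation pauses, vowel
elongation, delayed onsets, and occasional complete non-response. This
package turns each participant's twelve answers into a single composite
spectro-temporal image and trains a convolutional classifier to separate AD
from control participants.

Because real patient recordings are private, the package ships a first-class
**synthetic cohort generator**: seeded, language-agnostic syllable-burst
speech whose two classes differ only through interpretable acoustic symptom
knobs. Every downstream stage — standardization, feature imaging,
augmentation, training, evaluation — is developed and tested against it.

## The representation

Each answer is standardized to exactly 3 s at 44.1 kHz (132,300 samples;
shorter answers right-padded with silence, non-responses fully silent). With
25 ms frames (1103 samples, rounded half-up) hopped every 10 ms (441
samples), each clip yields per-frame mel-frequency cepstral coefficients
c₀…c₁₂ plus their delta (local regression slope) coefficients — a 26-row
feature matrix, min–max normalized to 8-bit gray and width-standardized to
599 columns. Stacking the twelve per-question images vertically gives one
**312 × 599 composite image** per participant, the classifier's input.

Training uses tenfold augmentation (brightness ±15%, rightward time shift up
to 20% of width — a "delayed response" effect) and the AdaMax optimizer
(batch size 4, ≤60 epochs, early stopping after 3 stale validation checks).
Evaluation reports the full diagnostic panel — sensitivity, specificity,
accuracy, PPV, NPV, F1, AUC (AD positive) — under a subject-wise 8:1:1
hold-out and five-fold cross-validation. Splits default to the
*participant* as the unit so augmented copies never straddle partitions; a
`paper_mode` switch reproduces the augment-then-split image-level protocol
instead.

## Worked example

```python
from voicescreen import RunConfig, SplitPlan, TrainConfig, run_all

cfg = RunConfig(n_per_class=16, seed=42, out_dir="scratch/demo",
                train=TrainConfig(learning_rate=1e-2, max_epochs=40, seed=0),
                split=SplitPlan(mode="holdout"))
summary = run_all(cfg)
```

prints (via `examples/05_full_pipeline.py`):

```
config hash 06bb369faa525e5a, seed 42
{"model": "small_cnn", "protocol": "holdout", "tp": 2, "fn": 0, "fp": 0,
 "tn": 2, "sensitivity": 1.0, "specificity": 1.0, "accuracy": 1.0,
 "ppv": 1.0, "npv": 1.0, "f1": 1.0, "auc": 1.0}
```

i.e. on the 4-participant held-out test set of this 32-participant cohort,
all four participants are classified correctly; `tp..tn` are the
confusion counts and the remaining fields the diagnostic panel. The
`examples/` scripts walk through each capability: cohort synthesis,
composite construction, augmentation, training/evaluation, full pipeline.

A thin CLI wraps the same library calls:

```bash
voicescreen run-all --n-per-class 40 --split holdout --seed 1 --out runs/r1
```

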