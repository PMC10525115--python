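"""From one spoken answer to the 312 x 599 composite training image.

Synthesizes one participant's 12 answers, standardizes each to exactly
3 s (132,300 samples), extracts 13 MFCCs + 13 deltas per 25 ms frame, and
stacks the twelve 26 x 599 per-question images into one composite.
"""

from voicescreen import (
    FrameSpec,
    MFCCImage,
    STARRED_QUESTIONS,
    composite_image,
    mfcc_with_deltas,
    save_png,
    standardize_clip,
    synth_response,
    to_image,
)
from voicescreen.features import frame_signal
from voicescreen.synth import ad_profile

spec = FrameSpec()
print(f"window {spec.win_samples} samples, hop {spec.hop_samples} samples")

tiles = []
for qid in STARRED_QUESTIONS:
    clip, responded = synth_response(ad_profile(), qid, seed=3)
    std = standardize_clip(clip, responded=responded)
    feats = mfcc_with_deltas(std, spec)
    print(f"question {qid:5s} responded={responded!s:5s} "
          f"frames={feats.shape[1]} feature rows={feats.shape[0]}")
    tiles.append(MFCCImage(to_image(feats, spec), qid))

comp = composite_image(tiles, participant_id="DEMO", group_label="AD")
save_png(comp.pixels, "scratch/demo_composite.png")
print(f"composite image: {comp.pixels.shape[0]} x {comp.pixels.shape[1]} "
      "(12 questions x 26 rows, width standardized to 599)")
# Unanswered questions appear as featureless bands: silence carries no
# spectral modulation, so its rows are constant along time.
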