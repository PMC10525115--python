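"""The twelve spoken-answer screening items that drive the pipeline.

The cognitive screening interview contains 28 items; twelve short
spoken-answer items (one temporal-orientation item, three memory-registration
items, five serial-subtraction items, three delayed-recall items) were
selected for acoustic analysis. Their fixed order defines, top to bottom, the
row bands of the composite feature image.
"""

from __future__ import annotations

STARRED_QUESTIONS: tuple[str, ...] = (
    "1-5",   # temporal orientation: current month
    "11-1",  # memory registration: tree
    "11-2",  # memory registration: car
    "11-3",  # memory registration: hat
    "12-1",  # serial subtraction 100-7
    "12-2",
    "12-3",
    "12-4",
    "12-5",
    "13-1",  # delayed recall: tree
    "13-2",  # delayed recall: car
    "13-3",  # delayed recall: hat
)

N_QUESTIONS = len(STARRED_QUESTIONS)

__all__ = ["STARRED_QUESTIONS", "N_QUESTIONS"]
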