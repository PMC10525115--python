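"""Standardization of raw responses to exactly 3 s, 44.1 kHz mono clips.

Every response, however long the participant took, becomes a clip of
exactly 132,300 samples: shorter answers are right-padded with digital
silence, longer recordings are truncated to their first 3 s, and a
non-response is represented as 3 s of pure silence regardless of what the
source file contains.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .audio import AudioClip, PIPELINE_RATE, read_wav, write_wav

STD_SECONDS = 3.0
STD_SAMPLES = 132_300  # 3 s at 44.1 kHz

__all__ = [
    "STD_SAMPLES",
    "STD_SECONDS",
    "StandardClip",
    "RateMismatchError",
    "downmix",
    "standardize_clip",
    "standardize_manifest",
]


class RateMismatchError(ValueError):
    """Raised when a clip is not sampled at the pipeline rate (no implicit
    resampling is performed)."""


@dataclass
class StandardClip:
    """A standardized mono response: exactly 132,300 samples at 44.1 kHz."""

    samples: np.ndarray
    source: tuple[str, str] = ("", "")  # (participant_id, question_id)
    responded: bool = True
    rate: int = PIPELINE_RATE

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.shape != (STD_SAMPLES,):
            raise ValueError(f"StandardClip must hold exactly {STD_SAMPLES} samples")
        if self.rate != PIPELINE_RATE:
            raise RateMismatchError(f"StandardClip rate must be {PIPELINE_RATE}")


def downmix(clip: AudioClip) -> AudioClip:
    """Mix a stereo clip to mono by per-sample channel mean.

    Mono input is returned unchanged; more than two channels is an error.
    """
    if clip.channels == 1:
        return clip
    if clip.channels == 2:
        return AudioClip(clip.samples.mean(axis=1), clip.rate)
    raise ValueError(f"unsupported channel count: {clip.channels}")


def standardize_clip(
    clip: AudioClip,
    responded: bool = True,
    source: tuple[str, str] = ("", ""),
) -> StandardClip:
    """Standardize one response to exactly 3 s.

    Rules: non-response -> 132,300 zeros whatever the input holds; shorter
    responses are right-padded with zeros; longer inputs keep their first
    3 s. Input must already be at 44.1 kHz.
    """
    if clip.rate != PIPELINE_RATE:
        raise RateMismatchError(
            f"expected {PIPELINE_RATE} Hz, got {clip.rate} Hz (resample upstream)"
        )
    if not responded:
        return StandardClip(np.zeros(STD_SAMPLES), source=source, responded=False)
    x = downmix(clip).samples
    if len(x) >= STD_SAMPLES:
        x = x[:STD_SAMPLES]
    else:
        x = np.concatenate([x, np.zeros(STD_SAMPLES - len(x))])
    return StandardClip(x, source=source, responded=True)


def standardize_manifest(
    responses: pd.DataFrame, out_dir: str | Path
) -> pd.DataFrame:
    """Standardize every clip of a cohort manifest.

    Reads each ``path``, writes the 3 s clip next to ``out_dir``, and
    returns the manifest with an added ``std_path`` column.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = responses.copy()
    std_paths = []
    for _, row in rows.iterrows():
        clip = read_wav(row["path"])
        std = standardize_clip(
            clip,
            responded=bool(row["responded"]),
            source=(row["participant_id"], str(row["question_id"])),
        )
        path = out / f"{row['participant_id']}_q{row['question_id']}_std.wav"
        write_wav(path, AudioClip(std.samples, std.rate))
        std_paths.append(str(path))
    rows["std_path"] = std_paths
    return rows
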