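"""Brightness and right-shift augmentation of composite feature images.

Only photometric (brightness) and temporal (rightward shift) operators are
used: geometric transforms would distort the pattern/texture cues that
encode speech characteristics. A right shift emulates a delayed response —
vacated columns are filled with silence-gray (128, the value a constant
silent feature band normalizes to). A seeded draw over the configured
brightness/shift grids expands the dataset by a fixed factor, copy 1 being
the untouched original.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .metrics import MetricsReport

SILENCE_GRAY = 128

__all__ = [
    "AugmentConfig",
    "SILENCE_GRAY",
    "adjust_brightness",
    "shift_right",
    "value_grid",
    "augment_set",
    "grid_validate",
]


@dataclass(frozen=True)
class AugmentConfig:
    """Augmentation operating ranges and expansion factor.

    Defaults are the validated settings: brightness within +-15% of the
    original, right shift up to 20% of the image width, tenfold expansion.
    """

    brightness_lo: float = 0.85
    brightness_hi: float = 1.15
    brightness_step: float = 0.05
    shift_max: float = 0.20
    shift_step: float = 0.05
    expansion_factor: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.brightness_lo <= 1.0 <= self.brightness_hi):
            raise ValueError("need 0 < brightness_lo <= 1 <= brightness_hi")
        if not (0.0 <= self.shift_max < 1.0):
            raise ValueError("shift_max must be in [0, 1)")
        if self.expansion_factor < 1:
            raise ValueError("expansion_factor must be >= 1")
        if self.brightness_step < 0 or self.shift_step < 0:
            raise ValueError("grid steps must be >= 0")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.__dict__, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AugmentConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def adjust_brightness(img: np.ndarray, factor: float) -> np.ndarray:
    """Scale pixel intensities by ``factor``, rounded and clamped to 8-bit."""
    if factor <= 0:
        raise ValueError("brightness factor must be > 0")
    return np.clip(np.rint(np.asarray(img, float) * factor), 0, 255).astype(np.uint8)


def shift_right(
    img: np.ndarray, fraction: float, fill: int = SILENCE_GRAY
) -> np.ndarray:
    """Shift image content right by ``round(fraction * width)`` columns.

    Vacated left columns take ``fill``; content shifted past the right edge
    is discarded (no wrap-around). Dimensions are unchanged.
    """
    if not (0.0 <= fraction < 1.0):
        raise ValueError("shift fraction must be in [0, 1)")
    img = np.asarray(img, dtype=np.uint8)
    width = img.shape[1]
    k = int(round(fraction * width))
    out = np.full_like(img, fill)
    if k < width:
        out[:, k:] = img[:, : width - k]
    return out


def value_grid(lo: float, hi: float, step: float) -> np.ndarray:
    """Inclusive arithmetic grid, robust to float step accumulation."""
    if step <= 0:
        return np.array([lo])
    n = int(round((hi - lo) / step)) + 1
    return np.round(lo + step * np.arange(n), 10)


def augment_set(
    images: list[np.ndarray],
    labels: list | np.ndarray,
    cfg: AugmentConfig = AugmentConfig(),
) -> tuple[list[np.ndarray], np.ndarray, pd.DataFrame]:
    """Expand a labeled image set by ``cfg.expansion_factor``.

    Copy 1 of each source is the original; further copies apply a seeded
    draw of (brightness, shift) from the configured grids. Returns
    ``(augmented_images, labels, provenance)`` where provenance records the
    source index and the applied factors for every output image.
    """
    if len(images) == 0:
        raise ValueError("augment_set needs a non-empty input")
    if len(images) != len(labels):
        raise ValueError("images and labels length mismatch")
    rng = np.random.default_rng(cfg.seed)
    b_grid = value_grid(cfg.brightness_lo, cfg.brightness_hi, cfg.brightness_step)
    s_grid = value_grid(0.0, cfg.shift_max, cfg.shift_step)
    out_images, out_labels, prov = [], [], []
    for idx, (img, lab) in enumerate(zip(images, labels)):
        out_images.append(np.asarray(img, dtype=np.uint8).copy())
        out_labels.append(lab)
        prov.append({"source_index": idx, "brightness": 1.0, "shift": 0.0})
        for _ in range(cfg.expansion_factor - 1):
            b = float(rng.choice(b_grid))
            s = float(rng.choice(s_grid))
            out_images.append(shift_right(adjust_brightness(img, b), s))
            out_labels.append(lab)
            prov.append({"source_index": idx, "brightness": b, "shift": s})
    return out_images, np.asarray(out_labels), pd.DataFrame(prov)


def grid_validate(
    images: list[np.ndarray],
    labels: np.ndarray,
    brightness_grid: np.ndarray | list[float],
    shift_grid: np.ndarray | list[float],
    train_eval_callback,
) -> pd.DataFrame:
    """Score each candidate augmentation setting with a train/eval callback.

    For every brightness factor (applied alone) and every shift fraction
    (applied alone), the original images plus one transformed copy each are
    handed to ``train_eval_callback(images, labels) -> MetricsReport``. The
    returned table has one row per setting with the full metric panel and a
    ``best`` flag on the top accuracy (F1 tie-break).
    """
    brightness_grid = list(brightness_grid or [])
    shift_grid = list(shift_grid or [])
    if not brightness_grid and not shift_grid:
        raise ValueError("both grids empty")
    rows = []
    for kind, grid in (("brightness", brightness_grid), ("shift", shift_grid)):
        for setting in grid:
            if kind == "brightness":
                copies = [adjust_brightness(img, setting) for img in images]
            else:
                copies = [shift_right(img, setting) for img in images]
            aug_images = list(images) + copies
            aug_labels = np.concatenate([labels, labels])
            report: MetricsReport = train_eval_callback(aug_images, aug_labels)
            rows.append({"kind": kind, "setting": float(setting), **report.panel()})
    table = pd.DataFrame(rows)
    ranked = table.sort_values(["accuracy", "f1"], ascending=False)
    table["best"] = False
    table.loc[ranked.index[0], "best"] = True
    return table
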