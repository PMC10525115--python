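"""MFCC(+delta) feature images and the 12-question composite.

Each standardized 3 s clip (132,300 samples at 44.1 kHz) is framed with a
25 ms window (1103 samples, half-up rounding) hopped every 10 ms (441
samples), giving 298 frames. Per frame, 13 mel-frequency cepstral
coefficients (orders 0-12, 26-filter mel bank, 2048-point FFT, Hamming
window, pre-emphasis 0.97) plus their 13 delta coefficients (9-frame local
linear-regression slope with edge replication) form a 26-row feature
matrix. The matrix is min-max normalized to 8-bit intensities and its time
axis linearly resampled to a standard width of 599 columns; the twelve
per-question images stacked vertically in the fixed question order give the
312 x 599 composite training image for one participant.

Note the width standardization: a 441-sample hop over 132,300 samples
cannot itself yield 599 frames; the 599-column geometry is met by
interpolation along time, keeping the stated hop arithmetic intact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image
from scipy.fft import dct, rfft

from .ingest import STD_SAMPLES, StandardClip
from .questions import STARRED_QUESTIONS

__all__ = [
    "FrameSpec",
    "MFCCImage",
    "CompositeImage",
    "frame_signal",
    "mfcc_with_deltas",
    "to_image",
    "composite_image",
    "save_png",
    "load_png",
    "featurize_manifest",
]

_LOG_FLOOR = 1e-10
_MID_GRAY = 128


@dataclass(frozen=True)
class FrameSpec:
    """Framing and cepstral analysis parameters.

    Defaults give 1103-sample windows (0.025 s at 44.1 kHz, rounded half-up)
    every 441 samples (0.01 s), 13 cepstra + 13 deltas, images 599 wide.
    """

    rate: int = 44_100
    win_dur: float = 0.025
    hop_dur: float = 0.01
    n_mfcc: int = 13
    n_mels: int = 26
    n_fft: int = 2048
    preemph: float = 0.97
    delta_window: int = 4  # regression half-width -> 9-frame window
    std_width: int = 599

    @property
    def win_samples(self) -> int:
        # half-up rounding: 0.025 * 44100 = 1102.5 -> 1103
        return int(np.floor(self.win_dur * self.rate + 0.5))

    @property
    def hop_samples(self) -> int:
        return int(round(self.hop_dur * self.rate))

    @property
    def n_rows(self) -> int:
        return self.n_mfcc * 2

    def __post_init__(self) -> None:
        if self.n_fft < self.win_samples:
            raise ValueError("n_fft must cover the analysis window")
        if self.n_mfcc > self.n_mels:
            raise ValueError("cannot take more cepstra than mel filters")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.__dict__, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FrameSpec":
        return cls(**yaml.safe_load(Path(path).read_text()))


@dataclass
class MFCCImage:
    """One question's 26 x 599 8-bit feature image."""

    pixels: np.ndarray
    question_id: str

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.uint8)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be 2-D")


@dataclass
class CompositeImage:
    """One participant's 312 x 599 stacked training image."""

    pixels: np.ndarray
    participant_id: str
    group_label: str
    row_order: tuple[str, ...] = STARRED_QUESTIONS

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.uint8)
        n = len(self.row_order)
        if self.pixels.shape[0] % n != 0:
            raise ValueError("composite height must tile evenly over questions")


def frame_signal(samples: np.ndarray | StandardClip, spec: FrameSpec = FrameSpec()) -> np.ndarray:
    """Slice a signal into overlapping analysis frames.

    Returns shape ``(n_frames, win_samples)`` with
    ``n_frames = 1 + floor((n - win) / hop)``; no padding past the signal
    end. A 132,300-sample clip yields 298 frames.
    """
    x = samples.samples if isinstance(samples, StandardClip) else np.asarray(samples, float)
    win, hop = spec.win_samples, spec.hop_samples
    if len(x) < win:
        raise ValueError(f"signal shorter than one frame ({len(x)} < {win})")
    starts = np.arange(0, len(x) - win + 1, hop)
    return np.lib.stride_tricks.sliding_window_view(x, win)[starts].copy()


def mel_filterbank(spec: FrameSpec = FrameSpec()) -> np.ndarray:
    """Triangular mel filterbank, shape ``(n_mels, n_fft // 2 + 1)``."""
    def hz_to_mel(f):
        return 2595.0 * np.log10(1.0 + np.asarray(f, float) / 700.0)

    def mel_to_hz(m):
        return 700.0 * (10.0 ** (np.asarray(m, float) / 2595.0) - 1.0)

    n_bins = spec.n_fft // 2 + 1
    mel_pts = np.linspace(hz_to_mel(0.0), hz_to_mel(spec.rate / 2.0), spec.n_mels + 2)
    hz_pts = mel_to_hz(mel_pts)
    bins = np.floor((spec.n_fft + 1) * hz_pts / spec.rate).astype(int)
    fb = np.zeros((spec.n_mels, n_bins))
    for m in range(1, spec.n_mels + 1):
        lo, ctr, hi = bins[m - 1], bins[m], bins[m + 1]
        for k in range(lo, ctr):
            fb[m - 1, k] = (k - lo) / max(ctr - lo, 1)
        for k in range(ctr, hi):
            fb[m - 1, k] = (hi - k) / max(hi - ctr, 1)
    return fb


def mel_energies(frames: np.ndarray, spec: FrameSpec = FrameSpec()) -> np.ndarray:
    """Per-frame mel filterbank energies, shape ``(n_frames, n_mels)``."""
    window = np.hamming(spec.win_samples)
    spectrum = rfft(frames * window, n=spec.n_fft, axis=1)
    power = np.abs(spectrum) ** 2 / spec.n_fft
    return power @ mel_filterbank(spec).T


def _delta(coeffs: np.ndarray, n: int) -> np.ndarray:
    """Local linear-regression slope over a ``2n+1``-frame window.

    Edge frames are replicated so the frame count is unchanged; a constant
    sequence has identically zero deltas.
    """
    padded = np.pad(coeffs, ((0, 0), (n, n)), mode="edge")
    denom = 2.0 * sum(i * i for i in range(1, n + 1))
    t = coeffs.shape[1]
    out = np.zeros_like(coeffs)
    for i in range(1, n + 1):
        out += i * (padded[:, n + i : n + i + t] - padded[:, n - i : n - i + t])
    return out / denom


def mfcc_with_deltas(
    clip: StandardClip | np.ndarray, spec: FrameSpec = FrameSpec()
) -> np.ndarray:
    """26 x T feature matrix: rows 0-12 cepstra, rows 13-25 their deltas."""
    x = clip.samples if isinstance(clip, StandardClip) else np.asarray(clip, float)
    emphasized = np.concatenate([x[:1], x[1:] - spec.preemph * x[:-1]])
    frames = frame_signal(emphasized, spec)
    logmel = np.log(np.maximum(mel_energies(frames, spec), _LOG_FLOOR))
    cepstra = dct(logmel, type=2, axis=1, norm="ortho")[:, : spec.n_mfcc].T
    return np.vstack([cepstra, _delta(cepstra, spec.delta_window)])


def to_image(features: np.ndarray, spec: FrameSpec = FrameSpec()) -> np.ndarray:
    """Min-max normalize a feature matrix to 8-bit and standardize width.

    A constant matrix maps to uniform mid-gray 128. Width is resampled to
    ``spec.std_width`` by linear interpolation along time; height is kept.
    """
    features = np.asarray(features, dtype=np.float64)
    if features.ndim != 2 or features.shape[1] < 2:
        raise ValueError("features must be 2-D with at least 2 frames")
    lo, hi = features.min(), features.max()
    if hi == lo:
        scaled = np.full_like(features, float(_MID_GRAY))
    else:
        scaled = (features - lo) / (hi - lo) * 255.0
    t_old = np.linspace(0.0, 1.0, features.shape[1])
    t_new = np.linspace(0.0, 1.0, spec.std_width)
    resampled = np.stack([np.interp(t_new, t_old, row) for row in scaled])
    return np.clip(np.rint(resampled), 0, 255).astype(np.uint8)


def composite_image(
    images: list[MFCCImage],
    participant_id: str = "",
    group_label: str = "",
    spec: FrameSpec = FrameSpec(),
) -> CompositeImage:
    """Stack the twelve per-question images into one composite.

    Tiles are placed in the fixed starred-question order (top to bottom)
    regardless of list order; the question-id set must be exactly complete
    and every tile 26 x ``std_width``.
    """
    if len(images) != len(STARRED_QUESTIONS):
        raise ValueError(f"need exactly {len(STARRED_QUESTIONS)} tiles, got {len(images)}")
    by_qid = {img.question_id: img for img in images}
    if set(by_qid) != set(STARRED_QUESTIONS):
        raise ValueError("question ids must match the starred set exactly")
    expected = (spec.n_rows, spec.std_width)
    for img in images:
        if img.pixels.shape != expected:
            raise ValueError(f"tile {img.question_id} has shape {img.pixels.shape}, expected {expected}")
    stacked = np.vstack([by_qid[q].pixels for q in STARRED_QUESTIONS])
    return CompositeImage(stacked, participant_id, group_label)


def save_png(pixels: np.ndarray, path: str | Path) -> None:
    """Write an 8-bit grayscale PNG."""
    Image.fromarray(np.asarray(pixels, dtype=np.uint8), mode="L").save(str(path))


def load_png(path: str | Path) -> np.ndarray:
    """Read an 8-bit grayscale PNG into a uint8 array."""
    return np.asarray(Image.open(str(path)).convert("L"), dtype=np.uint8)


def featurize_manifest(
    std_responses: pd.DataFrame,
    out_dir: str | Path,
    spec: FrameSpec = FrameSpec(),
) -> pd.DataFrame:
    """Build one composite PNG per participant from standardized clips.

    Expects the manifest from :func:`voicescreen.ingest.standardize_manifest`
    (columns ``participant_id, group, question_id, std_path, responded``).
    Returns an index frame with columns ``image_path, participant_id, group``
    and writes it as ``composites.csv`` beside the PNGs.
    """
    from .audio import read_wav

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for pid, grp in std_responses.groupby("participant_id", sort=True):
        tiles = []
        for _, row in grp.iterrows():
            clip = read_wav(row["std_path"])
            std = StandardClip(
                clip.samples, source=(pid, str(row["question_id"])),
                responded=bool(row["responded"]),
            )
            feats = mfcc_with_deltas(std, spec)
            tiles.append(MFCCImage(to_image(feats, spec), str(row["question_id"])))
        group = grp["group"].iloc[0]
        comp = composite_image(tiles, pid, group, spec)
        path = out / f"{pid}.png"
        save_png(comp.pixels, path)
        rows.append({"image_path": str(path), "participant_id": pid, "group": group})
    index = pd.DataFrame(rows)
    index.to_csv(out / "composites.csv", index=False)
    return index
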