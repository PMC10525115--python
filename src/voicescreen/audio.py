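"""Waveform container and 16-bit PCM WAV I/O.

All pipeline audio is 44.1 kHz; clips are float arrays in [-1, 1], mono
(shape ``(n,)``) or multi-channel (shape ``(n, channels)``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.io import wavfile

PIPELINE_RATE = 44_100

__all__ = ["AudioClip", "PIPELINE_RATE", "read_wav", "write_wav"]


@dataclass
class AudioClip:
    """A fixed-rate sampled waveform.

    Parameters
    ----------
    samples
        Amplitudes in [-1, 1]; shape ``(n,)`` for mono or ``(n, channels)``.
    rate
        Sampling rate in Hz (44,100 for all pipeline clips).
    """

    samples: np.ndarray
    rate: int = PIPELINE_RATE

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim not in (1, 2):
            raise ValueError("samples must be 1-D (mono) or 2-D (n, channels)")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if self.rate <= 0:
            raise ValueError("rate must be positive")

    @property
    def channels(self) -> int:
        return 1 if self.samples.ndim == 1 else self.samples.shape[1]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        """Clip length in seconds."""
        return self.n_samples / self.rate

    def as_stereo(self) -> "AudioClip":
        """Duplicate a mono clip into two identical channels."""
        if self.channels == 2:
            return self
        if self.channels != 1:
            raise ValueError("as_stereo expects mono or stereo input")
        return AudioClip(np.stack([self.samples, self.samples], axis=1), self.rate)


def write_wav(path: str | Path, clip: AudioClip) -> None:
    """Write a clip as 16-bit PCM WAV (amplitudes clipped to [-1, 1])."""
    x = np.clip(clip.samples, -1.0, 1.0)
    pcm = np.round(x * 32767.0).astype(np.int16)
    wavfile.write(str(path), clip.rate, pcm)


def read_wav(path: str | Path) -> AudioClip:
    """Read a WAV file into a float clip in [-1, 1]."""
    rate, data = wavfile.read(str(path))
    if data.dtype == np.int16:
        x = data.astype(np.float64) / 32767.0
    elif data.dtype == np.int32:
        x = data.astype(np.float64) / 2147483647.0
    elif data.dtype == np.uint8:
        x = (data.astype(np.float64) - 128.0) / 127.0
    else:  # already float
        x = data.astype(np.float64)
    return AudioClip(x, rate)
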