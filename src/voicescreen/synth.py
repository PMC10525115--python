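"""Seeded synthesis of two-class per-question voice-response cohorts.

Real screening recordings of dementia patients are private, so every
downstream stage is exercised on synthetic cohorts. Responses are
language-agnostic syllable-like bursts: a harmonic voiced source with a
smooth amplitude envelope plus a little breath noise, separated by gaps.
The two classes differ only through the acoustic symptom knobs of
:class:`SpeechProfile` — slowed tempo, elongated vowels, longer response
latency, more and longer inter-syllable pauses, and occasional complete
non-response (a silent clip).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .audio import AudioClip, PIPELINE_RATE, write_wav
from .questions import STARRED_QUESTIONS

__all__ = [
    "SpeechProfile",
    "EffectConfig",
    "CohortManifest",
    "synth_response",
    "make_cohort",
    "voiced_fraction",
    "ad_profile",
    "control_profile",
    "null_effect",
    "strong_effect",
]

# Base syllable timing at tempo_factor 1 (seconds); chosen so a fluent
# 2-4 syllable answer completes within 1-2 s.
_BASE_SYLL_DUR = 0.16
_BASE_GAP_DUR = 0.07


@dataclass(frozen=True)
class SpeechProfile:
    """Generative acoustic knobs for one speaker class (or one speaker).

    Parameters
    ----------
    group_label
        ``"AD"`` or ``"control"``.
    tempo_factor
        Syllable-rate multiplier (> 0); below 1 means slower speech.
    pause_prob
        Probability of inserting a pause at each inter-syllable gap.
    pause_dur_mean
        Mean pause duration in seconds (exponentially distributed).
    latency_mean
        Mean silence before the first syllable, seconds.
    f0_mean
        Mean fundamental frequency, Hz.
    f0_jitter
        Relative standard deviation of per-syllable f0.
    vowel_elong
        Vowel (syllable nucleus) duration multiplier (>= 1 for elongation).
    no_response_prob
        Probability that a question goes entirely unanswered (silent clip).
    """

    group_label: str = "control"
    tempo_factor: float = 1.0
    pause_prob: float = 0.05
    pause_dur_mean: float = 0.15
    latency_mean: float = 0.15
    f0_mean: float = 180.0
    f0_jitter: float = 0.02
    vowel_elong: float = 1.0
    no_response_prob: float = 0.0

    def __post_init__(self) -> None:
        for name in ("pause_prob", "no_response_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("tempo_factor", "vowel_elong", "f0_mean"):
            v = getattr(self, name)
            if not v > 0:
                raise ValueError(f"{name} must be > 0, got {v}")
        for name in ("pause_dur_mean", "latency_mean", "f0_jitter"):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")


def control_profile() -> SpeechProfile:
    """Prompt, fluent responder."""
    return SpeechProfile(group_label="control")


def ad_profile() -> SpeechProfile:
    """Hesitant, slow responder with pauses, elongated vowels and
    occasional complete non-response."""
    return SpeechProfile(
        group_label="AD",
        tempo_factor=0.6,
        pause_prob=0.5,
        pause_dur_mean=0.40,
        latency_mean=0.50,
        f0_mean=170.0,
        f0_jitter=0.06,
        vowel_elong=1.5,
        no_response_prob=0.20,
    )


@dataclass(frozen=True)
class EffectConfig:
    """Class-mean profiles plus between-speaker variability.

    ``speaker_jitter`` is the relative SD of the multiplicative lognormal
    jitter applied to each participant's positive-valued profile fields
    (tempo, durations, f0, elongation); probability fields get additive
    normal jitter of the same scale, clipped to [0, 1].
    """

    ad: SpeechProfile = field(default_factory=ad_profile)
    control: SpeechProfile = field(default_factory=control_profile)
    speaker_jitter: float = 0.10

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "ad": asdict(self.ad),
            "control": asdict(self.control),
            "speaker_jitter": self.speaker_jitter,
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "EffectConfig":
        doc = yaml.safe_load(Path(path).read_text())
        return cls(
            ad=SpeechProfile(**doc["ad"]),
            control=SpeechProfile(**doc["control"]),
            speaker_jitter=float(doc.get("speaker_jitter", 0.10)),
        )


def strong_effect() -> EffectConfig:
    """Default study conditions: clearly separated classes."""
    return EffectConfig()


def null_effect() -> EffectConfig:
    """Both classes share the control profile (labels only differ)."""
    ctl = control_profile()
    return EffectConfig(ad=replace(ctl, group_label="AD"), control=ctl)


@dataclass
class CohortManifest:
    """Participant roster and per-question response table.

    ``responses`` columns: participant_id, group, question_id, path,
    responded. Exactly twelve rows per participant, one per starred item.
    """

    participants: pd.DataFrame  # participant_id, group
    responses: pd.DataFrame

    def __post_init__(self) -> None:
        counts = self.responses.groupby("participant_id").size()
        if not (counts == len(STARRED_QUESTIONS)).all():
            raise ValueError("every participant needs exactly 12 response rows")
        qset = set(STARRED_QUESTIONS)
        for pid, grp in self.responses.groupby("participant_id"):
            if set(grp["question_id"]) != qset:
                raise ValueError(f"{pid}: question ids must match the starred set")
        if self.responses.duplicated(["participant_id", "question_id"]).any():
            raise ValueError("duplicate (participant, question) pair")

    def to_csv(self, path: str | Path) -> None:
        self.responses.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CohortManifest":
        resp = pd.read_csv(path, dtype={"question_id": str})
        resp["responded"] = resp["responded"].astype(bool)
        parts = resp[["participant_id", "group"]].drop_duplicates().reset_index(drop=True)
        return cls(parts, resp)


def _stable_seed(*parts) -> int:
    """Deterministic 31-bit seed from a tuple of printable parts."""
    return zlib.crc32(":".join(str(p) for p in parts).encode()) & 0x7FFFFFFF


def _syllable(dur: float, f0: float, rate: int, rng: np.random.Generator) -> np.ndarray:
    """One voiced burst: low harmonics under a Hann envelope + breath noise."""
    n = max(int(round(dur * rate)), 8)
    t = np.arange(n) / rate
    phase = rng.uniform(0, 2 * np.pi)
    x = np.zeros(n)
    for k in range(1, 6):
        x += np.sin(2 * np.pi * k * f0 * t + phase * k) / k
    x /= np.max(np.abs(x))
    env = np.hanning(n)
    noise = rng.normal(0.0, 0.03, n)
    return env * (x + noise)


def synth_response(
    profile: SpeechProfile, question_id: str, seed: int
) -> tuple[AudioClip, bool]:
    """Synthesize one question response.

    Returns the clip and a ``responded`` flag. A non-response draw yields a
    3 s silent clip with ``responded=False``. Output is a pure function of
    ``(profile, question_id, seed)``.
    """
    rng = np.random.default_rng(_stable_seed(seed, question_id, *asdict(profile).values()))
    rate = PIPELINE_RATE
    if rng.random() < profile.no_response_prob:
        return AudioClip(np.zeros(3 * rate), rate), False

    n_syll = int(rng.integers(2, 5))
    latency = max(0.0, rng.normal(profile.latency_mean, 0.2 * profile.latency_mean + 1e-9))
    pieces = [np.zeros(int(round(latency * rate)))]
    for i in range(n_syll):
        dur = (
            _BASE_SYLL_DUR
            * profile.vowel_elong
            / profile.tempo_factor
            * rng.lognormal(0.0, 0.15)
        )
        f0 = profile.f0_mean * (1.0 + profile.f0_jitter * rng.normal())
        pieces.append(_syllable(dur, max(f0, 40.0), rate, rng))
        if i < n_syll - 1:
            gap = _BASE_GAP_DUR / profile.tempo_factor
            if rng.random() < profile.pause_prob:
                gap += rng.exponential(profile.pause_dur_mean)
            pieces.append(np.zeros(int(round(gap * rate))))
    x = np.concatenate(pieces)
    x = x[: 3 * rate]  # keep the head; answers are front-loaded
    peak = np.max(np.abs(x))
    if peak > 0:
        x = 0.5 * x / peak
    return AudioClip(x, rate), True


def _jitter_profile(
    mean: SpeechProfile, jitter: float, rng: np.random.Generator
) -> SpeechProfile:
    """Draw one participant's profile around the class mean."""
    def mult(v: float) -> float:
        return float(v * rng.lognormal(0.0, jitter))

    def prob(v: float) -> float:
        return float(np.clip(v + jitter * rng.normal() * max(v, 0.05), 0.0, 1.0))

    return SpeechProfile(
        group_label=mean.group_label,
        tempo_factor=mult(mean.tempo_factor),
        pause_prob=prob(mean.pause_prob),
        pause_dur_mean=mult(mean.pause_dur_mean) if mean.pause_dur_mean > 0 else 0.0,
        latency_mean=mult(mean.latency_mean) if mean.latency_mean > 0 else 0.0,
        f0_mean=mult(mean.f0_mean),
        f0_jitter=mean.f0_jitter,
        vowel_elong=max(mult(mean.vowel_elong), 1.0),
        no_response_prob=prob(mean.no_response_prob),
    )


def make_cohort(
    n_per_class: int,
    effect_config: EffectConfig,
    seed: int,
    out_dir: str | Path,
) -> CohortManifest:
    """Generate a balanced two-class cohort of WAV responses.

    Writes ``2 * n_per_class * 12`` mono 16-bit PCM WAV files plus
    ``manifest.csv`` under ``out_dir`` and returns the manifest. Generation
    is a pure function of ``(n_per_class, effect_config, seed)``.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    part_rows, resp_rows = [], []
    for group, mean in (("AD", effect_config.ad), ("control", effect_config.control)):
        for i in range(n_per_class):
            pid = f"{'AD' if group == 'AD' else 'CTL'}{i + 1:03d}"
            prof = _jitter_profile(
                mean, effect_config.speaker_jitter,
                np.random.default_rng(_stable_seed(seed, "profile", pid)),
            )
            part_rows.append({"participant_id": pid, "group": group})
            for qid in STARRED_QUESTIONS:
                clip, responded = synth_response(prof, qid, _stable_seed(seed, "resp", pid, qid))
                path = out / f"{pid}_q{qid}.wav"
                write_wav(path, clip)
                resp_rows.append(
                    {
                        "participant_id": pid,
                        "group": group,
                        "question_id": qid,
                        "path": str(path),
                        "responded": responded,
                    }
                )
    manifest = CohortManifest(pd.DataFrame(part_rows), pd.DataFrame(resp_rows))
    manifest.to_csv(out / "manifest.csv")
    return manifest


def voiced_fraction(
    clip: AudioClip, win: int = 1103, hop: int = 441, threshold: float = 0.02
) -> float:
    """Fraction of analysis frames whose RMS exceeds ``threshold``.

    Frame-energy thresholding; serves as a simple model-free measure of how
    much of a clip is voiced (used to verify class separation).
    """
    x = clip.samples if clip.samples.ndim == 1 else clip.samples.mean(axis=1)
    if len(x) < win:
        return 0.0
    starts = np.arange(0, len(x) - win + 1, hop)
    frames = np.lib.stride_tricks.sliding_window_view(x, win)[starts]
    rms = np.sqrt((frames**2).mean(axis=1))
    return float((rms > threshold).mean())
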