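"""MFCC feature images: framing arithmetic, deltas, layout, composites."""

import numpy as np
import pytest

from voicescreen.audio import PIPELINE_RATE
from voicescreen.features import (
    CompositeImage,
    FrameSpec,
    MFCCImage,
    composite_image,
    frame_signal,
    load_png,
    mel_energies,
    mfcc_with_deltas,
    save_png,
    to_image,
)
from voicescreen.ingest import STD_SAMPLES, StandardClip
from voicescreen.questions import STARRED_QUESTIONS

SPEC = FrameSpec()


def _tone_std(freq: float) -> StandardClip:
    t = np.arange(STD_SAMPLES) / PIPELINE_RATE
    return StandardClip(0.4 * np.sin(2 * np.pi * freq * t))


class TestFraming:
    def test_spec_arithmetic(self):
        assert SPEC.win_samples == 1103  # 0.025 * 44100 rounded half-up
        assert SPEC.hop_samples == 441
        assert SPEC.n_rows == 26

    def test_standard_clip_frame_count(self, std_tone):
        frames = frame_signal(std_tone, SPEC)
        # oracle: enumerate frame starts
        expected = len(range(0, STD_SAMPLES - 1103 + 1, 441))
        assert expected == 298
        assert frames.shape == (298, 1103)

    def test_single_frame(self):
        frames = frame_signal(np.ones(1103), SPEC)
        assert frames.shape == (1, 1103)

    def test_zero_clip_zero_frames(self):
        frames = frame_signal(np.zeros(5000), SPEC)
        assert np.all(frames == 0)

    def test_too_short_signal(self):
        with pytest.raises(ValueError):
            frame_signal(np.zeros(500), SPEC)

    def test_frames_match_manual_slices(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=4000)
        frames = frame_signal(x, SPEC)
        for i in range(frames.shape[0]):
            np.testing.assert_array_equal(frames[i], x[i * 441 : i * 441 + 1103])


class TestMFCC:
    def test_silence_has_constant_cepstra_zero_deltas(self, silence_std):
        feats = mfcc_with_deltas(silence_std, SPEC)
        assert feats.shape == (26, 298)
        # every frame identical
        assert np.allclose(feats[:13], feats[:13, :1])
        np.testing.assert_allclose(feats[13:], 0.0, atol=1e-12)

    def test_row_count_is_26(self, std_tone):
        assert mfcc_with_deltas(std_tone, SPEC).shape[0] == 26

    def test_tones_separate_in_filterbank_and_cepstra(self):
        """Oracle: direct mel filterbank energies locate 1 kHz and 4 kHz in
        different bands; the cepstra must differ accordingly."""
        lo, hi = _tone_std(1000.0), _tone_std(4000.0)
        e_lo = mel_energies(frame_signal(lo.samples, SPEC), SPEC).mean(axis=0)
        e_hi = mel_energies(frame_signal(hi.samples, SPEC), SPEC).mean(axis=0)
        assert np.argmax(e_lo) != np.argmax(e_hi)
        # independent check of the band ordering on the mel scale
        def mel(f):
            return 2595 * np.log10(1 + f / 700)
        centers = np.linspace(mel(0), mel(PIPELINE_RATE / 2), SPEC.n_mels + 2)[1:-1]
        assert np.argmin(np.abs(centers - mel(1000))) < np.argmin(np.abs(centers - mel(4000)))
        assert np.argmax(e_lo) < np.argmax(e_hi)
        assert not np.allclose(mfcc_with_deltas(lo, SPEC), mfcc_with_deltas(hi, SPEC))


class TestToImage:
    def test_geometry(self, std_tone):
        img = to_image(mfcc_with_deltas(std_tone, SPEC), SPEC)
        assert img.shape == (26, 599)
        assert img.dtype == np.uint8

    def test_constant_maps_to_mid_gray(self):
        img = to_image(np.full((26, 100), 7.0), SPEC)
        assert np.all(img == 128)

    def test_minmax_range_used_fully(self, std_tone):
        img = to_image(mfcc_with_deltas(std_tone, SPEC), SPEC)
        assert img.min() == 0 and img.max() == 255

    def test_width_599_identity_up_to_rounding(self):
        rng = np.random.default_rng(0)
        feats = rng.normal(size=(26, 599))
        img = to_image(feats, SPEC)
        direct = np.clip(
            np.rint((feats - feats.min()) / (feats.max() - feats.min()) * 255), 0, 255
        )
        assert np.max(np.abs(img.astype(int) - direct.astype(int))) <= 1

    def test_rejects_single_frame(self):
        with pytest.raises(ValueError):
            to_image(np.zeros((26, 1)), SPEC)


def _tiles(fill=None):
    rng = np.random.default_rng(1)
    tiles = []
    for q in STARRED_QUESTIONS:
        px = rng.integers(0, 256, size=(26, 599), dtype=np.uint8)
        if fill is not None:
            px = np.full((26, 599), fill, dtype=np.uint8)
        tiles.append(MFCCImage(px, q))
    return tiles


class TestComposite:
    def test_geometry(self):
        comp = composite_image(_tiles(), "P1", "AD")
        assert comp.pixels.shape == (312, 599)
        assert comp.row_order == STARRED_QUESTIONS

    def test_missing_tile_rejected(self):
        with pytest.raises(ValueError):
            composite_image(_tiles()[:11])

    def test_duplicate_question_rejected(self):
        tiles = _tiles()
        tiles[1] = MFCCImage(tiles[1].pixels, tiles[0].question_id)
        with pytest.raises(ValueError):
            composite_image(tiles)

    def test_wrong_tile_size_rejected(self):
        tiles = _tiles()
        tiles[0] = MFCCImage(np.zeros((26, 100), dtype=np.uint8), tiles[0].question_id)
        with pytest.raises(ValueError):
            composite_image(tiles)

    @pytest.mark.parametrize("k", [0, 5, 11])
    def test_tile_locality(self, k):
        """Zeroing tile k blanks exactly rows 26k..26k+25."""
        tiles = _tiles()
        base = composite_image(tiles).pixels
        qid = STARRED_QUESTIONS[k]
        tiles[k] = MFCCImage(np.zeros((26, 599), dtype=np.uint8), qid)
        changed = composite_image(tiles).pixels
        assert np.all(changed[26 * k : 26 * (k + 1)] == 0)
        mask = np.ones(312, dtype=bool)
        mask[26 * k : 26 * (k + 1)] = False
        np.testing.assert_array_equal(changed[mask], base[mask])

    def test_input_order_irrelevant(self):
        tiles = _tiles()
        shuffled = list(reversed(tiles))
        np.testing.assert_array_equal(
            composite_image(tiles).pixels, composite_image(shuffled).pixels
        )

    def test_silence_band_uniform_voiced_band_not(self, silence_std, std_tone):
        sil = to_image(mfcc_with_deltas(silence_std, SPEC), SPEC)
        voiced = to_image(mfcc_with_deltas(std_tone, SPEC), SPEC)
        # a silent band is featureless along time (every column identical);
        # a voiced band varies over time
        assert np.all(sil == sil[:, :1])
        assert np.any(voiced != voiced[:, :1])

    def test_png_roundtrip(self, tmp_path):
        comp = composite_image(_tiles(), "P1", "AD")
        path = tmp_path / "comp.png"
        save_png(comp.pixels, path)
        np.testing.assert_array_equal(load_png(path), comp.pixels)
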