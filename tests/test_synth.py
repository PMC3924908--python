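"""Calibrated synthesis: tones, filtered noise, AM, mixing, file round trips."""

import math
import wave as wave_mod

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.signal import welch

from tinnsynth.models import (
    AMSpec,
    Ear,
    NoiseComponent,
    RenderConfig,
    TinnitusModel,
    ToneComponent,
)
from tinnsynth.synth import (
    ProjectFormatError,
    apply_am,
    load_project,
    measure_level_db_spl,
    render,
    save_project,
    synthesize_noise,
    synthesize_tone,
    write_wave,
)


class TestTone:
    @pytest.mark.parametrize(
        "frequency,level",
        [(2724.0, 35.5), (1000.0, 60.0), (82.0, 88.4), (6172.0, 79.0)],
    )
    def test_level_calibration(self, config, frequency, level):
        y = synthesize_tone(ToneComponent(frequency_hz=frequency, level_db_spl=level), config)
        assert len(y) == config.n_samples == 132300
        assert measure_level_db_spl(y, config) == pytest.approx(level, abs=0.5)

    def test_full_scale_at_calibration_offset(self, config):
        tone = ToneComponent(frequency_hz=1000.0, level_db_spl=config.calibration_offset_db)
        y = synthesize_tone(tone, config)
        # sinusoid amplitude is exactly full scale (the sampled peak sits
        # within one sample of the crest)
        assert np.sqrt(2 * np.mean(y**2)) == pytest.approx(1.0, rel=1e-9)
        assert np.max(np.abs(y)) == pytest.approx(1.0, abs=1e-3)

    def test_energy_concentrated_at_tone_bin(self, config):
        y = synthesize_tone(ToneComponent(frequency_hz=1000.0, level_db_spl=60.0), config)
        spec = np.abs(np.fft.rfft(y)) ** 2
        k = round(1000.0 * config.duration_s)
        assert np.argmax(spec) == k
        assert spec[k - 1 : k + 2].sum() / spec.sum() > 0.99

    def test_rejects_frequency_above_nyquist(self, config):
        # the type itself caps frequency at 22 kHz ...
        with pytest.raises(ValueError, match="frequency_hz"):
            ToneComponent(frequency_hz=22050.0, level_db_spl=60.0)
        # ... and the synthesis path guards Nyquist independently
        hot = ToneComponent.model_construct(
            frequency_hz=23000.0, level_db_spl=60.0, am=None
        )
        with pytest.raises(ValueError, match="Nyquist"):
            synthesize_tone(hot, config)

    @pytest.mark.parametrize("k", [1, 5, 20])
    def test_calibration_linearity(self, config, k):
        base = synthesize_tone(ToneComponent(frequency_hz=750.0, level_db_spl=40.0), config)
        up = synthesize_tone(ToneComponent(frequency_hz=750.0, level_db_spl=40.0 + k), config)
        rms = lambda x: np.sqrt(np.mean(x**2))
        assert rms(up) / rms(base) == pytest.approx(10 ** (k / 20), rel=1e-9)


class TestNoise:
    def test_level_calibration(self, config, bank):
        noise = NoiseComponent(band_low_hz=350.0, band_high_hz=2100.0, level_db_spl=31.6)
        y = synthesize_noise(noise, config, bank)
        assert measure_level_db_spl(y, config) == pytest.approx(31.6, abs=0.5)

    def test_out_of_band_rejection(self, config, bank):
        noise = NoiseComponent(band_low_hz=350.0, band_high_hz=2100.0, level_db_spl=60.0)
        y = synthesize_noise(noise, config, bank)
        f, psd = welch(y, fs=config.sample_rate_hz, nperseg=4096)
        inband = psd[(f > 500) & (f < 1800)].mean()
        outband = psd[(f > 6000) & (f < 18000)].mean()
        assert 10 * np.log10(inband / outband) >= 40.0

    def test_full_range_noise_is_spectrally_flat(self, config, bank):
        lo, hi = bank.coverage_hz
        noise = NoiseComponent(band_low_hz=lo, band_high_hz=hi, level_db_spl=70.0)
        y = synthesize_noise(noise, config, bank)
        f, psd = welch(y, fs=config.sample_rate_hz, nperseg=2048)
        centers = (bank.bands[0].center_hz, bank.bands[-1].center_hz)
        sel = (f >= centers[0]) & (f <= centers[1])
        level = 10 * np.log10(psd[sel])
        assert level.max() - level.min() <= 6.0  # flat within +/-3 dB

    def test_seeded_determinism(self, config, bank):
        noise = NoiseComponent(band_low_hz=900.0, band_high_hz=2400.0, level_db_spl=52.2)
        a = synthesize_noise(noise, config, bank, seed=7)
        b = synthesize_noise(noise, config, bank, seed=7)
        assert np.array_equal(a, b)
        c = synthesize_noise(noise, config, bank, seed=8)
        assert not np.array_equal(a, c)

    def test_band_outside_coverage_rejected(self, config, bank):
        noise = NoiseComponent(band_low_hz=2.0, band_high_hz=20.0, level_db_spl=50.0)
        with pytest.raises(ValueError, match="coverage"):
            synthesize_noise(noise, config, bank)


class TestAM:
    def test_zero_depth_is_identity(self, config):
        y = synthesize_tone(ToneComponent(frequency_hz=500.0, level_db_spl=60.0), config)
        out = apply_am(y, AMSpec(rate_hz=4.0, depth=0.0), config)
        assert np.array_equal(out, y)

    def test_full_depth_envelope_reaches_zero(self, config):
        y = np.ones(config.n_samples)
        out = apply_am(y, AMSpec(rate_hz=2.0, depth=1.0), config)
        assert out.min() == pytest.approx(0.0, abs=1e-9)
        assert out.max() == pytest.approx(1.0, abs=1e-9)

    def test_hilbert_envelope_tracks_modulator(self, config):
        from scipy.signal import hilbert

        y = synthesize_tone(ToneComponent(frequency_hz=1000.0, level_db_spl=100.0), config)
        out = apply_am(y, AMSpec(rate_hz=4.0, depth=0.5), config)
        env = np.abs(hilbert(out))
        mid = env[2000:-2000]  # discard Hilbert edge transients
        assert mid.max() == pytest.approx(1.0, abs=0.01)
        assert mid.min() == pytest.approx(0.5, abs=0.01)
        # envelope oscillates at the modulation rate
        spec = np.abs(np.fft.rfft(mid - mid.mean()))
        peak_hz = np.argmax(spec) / (len(mid) / config.sample_rate_hz)
        assert peak_hz == pytest.approx(4.0, abs=0.15)

    @given(depth=st.floats(min_value=0.0, max_value=1.0))
    @settings(max_examples=30, deadline=None)
    def test_rms_matches_closed_form(self, depth):
        config = RenderConfig(duration_s=1.0)
        y = synthesize_tone(ToneComponent(frequency_hz=1000.0, level_db_spl=80.0), config)
        out = apply_am(y, AMSpec(rate_hz=4.0, depth=depth), config) if depth else y
        ratio = np.sqrt(np.mean(out**2) / np.mean(y**2))
        expected = math.sqrt(1 - depth + 3 * depth**2 / 8)
        assert ratio == pytest.approx(expected, rel=0.01)


class TestRender:
    def test_single_ear_routing_leaves_other_channel_zero(self, config):
        tones = tuple(
            ToneComponent(frequency_hz=f, level_db_spl=l)
            for f, l in [(82.0, 88.4), (361.0, 65.5), (1281.0, 39.0)]
        )
        r = render(TinnitusModel(tones=tones, ear=Ear.left), config)
        assert np.all(r.buffer[:, 1] == 0.0)
        assert np.any(r.buffer[:, 0] != 0.0)

    def test_both_ears_identical(self, config):
        m = TinnitusModel(tones=(ToneComponent(frequency_hz=440.0, level_db_spl=50.0),))
        r = render(m, config)
        assert np.array_equal(r.buffer[:, 0], r.buffer[:, 1])

    def test_two_equal_tones_add_3db(self, config):
        one = TinnitusModel(tones=(ToneComponent(frequency_hz=1000.0, level_db_spl=60.0),))
        two = TinnitusModel(
            tones=(
                ToneComponent(frequency_hz=1000.0, level_db_spl=60.0),
                ToneComponent(frequency_hz=1500.0, level_db_spl=60.0),
            )
        )
        l1 = render(one, config).channel_levels_db_spl[0]
        l2 = render(two, config).channel_levels_db_spl[0]
        assert l2 - l1 == pytest.approx(10 * math.log10(2), abs=0.05)

    def test_hot_mix_is_normalized_with_reported_gain(self, config):
        m = TinnitusModel(
            tones=(
                ToneComponent(frequency_hz=1000.0, level_db_spl=99.0),
                ToneComponent(frequency_hz=1700.0, level_db_spl=99.0),
            )
        )
        r = render(m, config)
        assert r.gain_db < 0.0
        assert np.max(np.abs(r.buffer)) <= 1.0


class TestFiles:
    def test_wave_header_of_3s_stereo_render(self, tmp_path, config):
        m = TinnitusModel(tones=(ToneComponent(frequency_hz=1000.0, level_db_spl=60.0),))
        write_wave(render(m, config).buffer, tmp_path / "out.wav", config)
        with wave_mod.open(str(tmp_path / "out.wav")) as wf:
            assert wf.getframerate() == 44100
            assert wf.getnchannels() == 2
            assert wf.getsampwidth() == 2
            assert wf.getnframes() == 132300

    def test_project_round_trip(self, tmp_path):
        model = TinnitusModel(
            tones=(
                ToneComponent(
                    frequency_hz=2724.0,
                    level_db_spl=35.5,
                    am=AMSpec(rate_hz=3.0, depth=0.7),
                ),
            ),
            noises=(NoiseComponent(band_low_hz=8900.0, band_high_hz=10400.0, level_db_spl=44.5),),
            ear=Ear.right,
        )
        config = RenderConfig(duration_s=2.0, calibration_offset_db=95.0, rng_seed=42)
        save_project(model, config, tmp_path / "p.json")
        model2, config2 = load_project(tmp_path / "p.json")
        assert model2 == model
        assert config2 == config

    def test_malformed_project_names_offending_field(self, tmp_path):
        (tmp_path / "bad.json").write_text(
            '{"version": 1, "ear": "both", '
            '"tones": [{"frequency_hz": -5, "level_db_spl": 60}], "noises": []}'
        )
        with pytest.raises(ProjectFormatError, match="frequency_hz"):
            load_project(tmp_path / "bad.json")

    def test_wrong_version_rejected(self, tmp_path):
        (tmp_path / "v9.json").write_text('{"version": 9, "tones": []}')
        with pytest.raises(ProjectFormatError, match="version"):
            load_project(tmp_path / "v9.json")
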