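"""Calibrated audio synthesis: tones, filtered noise, AM, mixing, file I/O.

Calibration convention: a full-scale sinusoid (peak amplitude 1.0,
RMS 1/sqrt(2)) represents ``calibration_offset_db`` dB SPL.  The digital level
of any buffer is therefore ``cal + 20·log10(rms·sqrt(2))``, and component
levels are realised by scaling to the corresponding RMS.  For AM components
the carrier is calibrated before modulation; the raised-cosine modulator
lowers long-run RMS by the closed-form factor
``sqrt(1 - depth + 3·depth²/8)``.
"""

from __future__ import annotations

import json
import math
import wave
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from pydantic import ValidationError
from scipy import signal

from .filterbank import Filterbank, default_filterbank
from .models import (
    AMSpec,
    Ear,
    NoiseComponent,
    RenderConfig,
    TinnitusModel,
    ToneComponent,
)

PROJECT_FORMAT_VERSION = 1

__all__ = [
    "ProjectFormatError",
    "RenderResult",
    "apply_am",
    "load_project",
    "measure_level_db_spl",
    "render",
    "save_project",
    "synthesize_noise",
    "synthesize_tone",
    "write_wave",
]


class ProjectFormatError(ValueError):
    """A project file failed validation; the message names the offending field."""


def _target_rms(level_db_spl: float, config: RenderConfig) -> float:
    return 10.0 ** ((level_db_spl - config.calibration_offset_db) / 20.0) / math.sqrt(2.0)


def measure_level_db_spl(buffer: np.ndarray, config: RenderConfig) -> float:
    """Digital dB SPL of a buffer under the calibration convention."""
    rms = float(np.sqrt(np.mean(np.square(buffer, dtype=float))))
    if rms <= 0.0:
        return -math.inf
    return config.calibration_offset_db + 20.0 * math.log10(rms * math.sqrt(2.0))


def apply_am(buffer: np.ndarray, am: AMSpec, config: RenderConfig) -> np.ndarray:
    """Amplitude-modulate with m(t) = 1 - (depth/2)·(1 - cos(2π·rate·t)).

    The envelope peaks at 1 (level at modulation maxima is preserved) and
    dips to ``1 - depth``.
    """
    t = np.arange(len(buffer)) / config.sample_rate_hz
    m = 1.0 - (am.depth / 2.0) * (1.0 - np.cos(2.0 * np.pi * am.rate_hz * t))
    return buffer * m


def synthesize_tone(tone: ToneComponent, config: RenderConfig) -> np.ndarray:
    """Render a calibrated pure tone (mono float64, peak 1.0 at full scale)."""
    nyquist = config.sample_rate_hz / 2.0
    if tone.frequency_hz >= nyquist:
        raise ValueError(
            f"tone frequency {tone.frequency_hz} Hz is at or above the "
            f"Nyquist frequency {nyquist} Hz for fs={config.sample_rate_hz}"
        )
    amplitude = 10.0 ** ((tone.level_db_spl - config.calibration_offset_db) / 20.0)
    t = np.arange(config.n_samples) / config.sample_rate_hz
    y = amplitude * np.sin(2.0 * np.pi * tone.frequency_hz * t)
    if tone.am is not None:
        y = apply_am(y, tone.am, config)
    return y


def synthesize_noise(
    noise: NoiseComponent,
    config: RenderConfig,
    bank: Filterbank | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """Render calibrated band-limited noise through the 1/8-octave filterbank.

    Seeded Gaussian white noise (clipped at ±4σ) is filtered through the
    coherent union of the filterbank bands that intersect the requested band,
    then scaled to the target overall level.  The generator is seeded from
    ``seed`` (default ``config.rng_seed``), so identical inputs give identical
    buffers.
    """
    bank = bank or default_filterbank()
    indices = bank.band_indices_overlapping(noise.band_low_hz, noise.band_high_hz)
    if not indices:
        lo, hi = bank.coverage_hz
        raise ValueError(
            f"noise band {noise.band_low_hz}-{noise.band_high_hz} Hz lies outside "
            f"filterbank coverage {lo:.0f}-{hi:.0f} Hz"
        )
    h = bank.combined_coefficients(indices)
    rng = np.random.default_rng(config.rng_seed if seed is None else seed)
    # extra samples so 'valid' convolution returns a steady-state buffer
    x = rng.standard_normal(config.n_samples + len(h) - 1)
    np.clip(x, -4.0, 4.0, out=x)
    y = signal.fftconvolve(x, h, mode="valid")
    rms = float(np.sqrt(np.mean(y**2)))
    y *= _target_rms(noise.level_db_spl, config) / rms
    if noise.am is not None:
        y = apply_am(y, noise.am, config)
    return y


@dataclass(frozen=True)
class RenderResult:
    """A stereo render: samples of shape (n, 2) plus the anti-clip gain."""

    buffer: np.ndarray
    gain_db: float  # 0.0 unless the mix had to be scaled down
    channel_levels_db_spl: tuple[float, float]


def render(
    model: TinnitusModel,
    config: RenderConfig | None = None,
    bank: Filterbank | None = None,
) -> RenderResult:
    """Mix all components into a stereo buffer with ear routing.

    The silent channel of a one-ear model is exactly zero; ``ear=both``
    copies the identical mono mix into both channels.  If the summed peak
    exceeds full scale the whole mix is scaled down and the applied gain
    reported in ``gain_db`` (negative dB).
    """
    config = config or RenderConfig()
    mono = np.zeros(config.n_samples)
    noise_streams = np.random.SeedSequence(config.rng_seed).spawn(len(model.noises))
    for tone in model.tones:
        mono += synthesize_tone(tone, config)
    for noise, ss in zip(model.noises, noise_streams):
        sub_seed = int(ss.generate_state(1)[0] % (2**31))
        mono += synthesize_noise(noise, config, bank=bank, seed=sub_seed)

    gain_db = 0.0
    peak = float(np.max(np.abs(mono))) if mono.size else 0.0
    if peak > 1.0:
        mono = mono / peak
        gain_db = -20.0 * math.log10(peak)

    stereo = np.zeros((config.n_samples, 2))
    if model.ear in (Ear.left, Ear.both):
        stereo[:, 0] = mono
    if model.ear in (Ear.right, Ear.both):
        stereo[:, 1] = mono
    levels = tuple(measure_level_db_spl(stereo[:, c], config) for c in (0, 1))
    return RenderResult(buffer=stereo, gain_db=gain_db, channel_levels_db_spl=levels)


def write_wave(buffer: np.ndarray, path: str | Path, config: RenderConfig | None = None) -> None:
    """Write a mono or stereo float buffer as 16-bit PCM RIFF WAVE at 44.1 kHz."""
    config = config or RenderConfig()
    data = np.asarray(buffer, dtype=float)
    if data.ndim == 1:
        data = data[:, None]
    pcm = np.clip(np.round(data * 32767.0), -32768, 32767).astype("<i2")
    with wave.open(str(path), "wb") as wf:
        wf.setnchannels(pcm.shape[1])
        wf.setsampwidth(2)
        wf.setframerate(config.sample_rate_hz)
        wf.writeframes(pcm.tobytes())


def _model_to_dict(model: TinnitusModel) -> dict:
    def comp(c):
        d = c.model_dump(exclude_none=True)
        return d

    return {
        "ear": model.ear.value,
        "tones": [comp(t) for t in model.tones],
        "noises": [comp(n) for n in model.noises],
    }


def save_project(
    model: TinnitusModel, config: RenderConfig, path: str | Path
) -> None:
    """Save a re-loadable JSON project file (model + render configuration)."""
    doc = {
        "version": PROJECT_FORMAT_VERSION,
        **_model_to_dict(model),
        "config": {
            "duration_s": config.duration_s,
            "calibration_offset_db": config.calibration_offset_db,
            "rng_seed": config.rng_seed,
        },
    }
    Path(path).write_text(json.dumps(doc, indent=2))


def load_project(path: str | Path) -> tuple[TinnitusModel, RenderConfig]:
    """Load a project file; raises :class:`ProjectFormatError` naming bad fields."""
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ProjectFormatError(f"not valid JSON: {exc}") from exc
    if not isinstance(doc, dict):
        raise ProjectFormatError("project root must be a JSON object")
    version = doc.get("version")
    if version != PROJECT_FORMAT_VERSION:
        raise ProjectFormatError(
            f"field 'version': expected {PROJECT_FORMAT_VERSION}, got {version!r}"
        )
    try:
        model = TinnitusModel(
            tones=tuple(ToneComponent(**t) for t in doc.get("tones", [])),
            noises=tuple(NoiseComponent(**n) for n in doc.get("noises", [])),
            ear=doc.get("ear", "both"),
        )
        config = RenderConfig(**doc.get("config", {}))
    except ValidationError as exc:
        first = exc.errors()[0]
        loc = ".".join(str(p) for p in first["loc"]) or "<root>"
        raise ProjectFormatError(f"field '{loc}': {first['msg']}") from exc
    except (TypeError, ValueError) as exc:
        raise ProjectFormatError(str(exc)) from exc
    return model, config
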