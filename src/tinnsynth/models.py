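"""Domain types for tinnitus sound models and rendering.

A :class:`TinnitusModel` is the unit of both synthesis and matching: a set of
pure-tone and band-limited-noise components, each with a sound-pressure level
and optional amplitude modulation, routed to one or both ears.  Levels are
digital dB SPL under a configurable calibration convention (see
:class:`RenderConfig`).
"""

from __future__ import annotations

import math
from enum import Enum
from typing import Literal, Optional, Union

from pydantic import BaseModel, Field, model_validator

SAMPLE_RATE_HZ = 44100
MAX_FREQUENCY_HZ = 22000.0


class Ear(str, Enum):
    """Ear routing of a rendered model."""

    left = "left"
    right = "right"
    both = "both"


class AMSpec(BaseModel):
    """Amplitude modulation: a 'pulsing' or 'throbbing' character.

    ``rate_hz`` is the modulation frequency (the perceptual slow/fast axis,
    roughly 0.5-8 Hz for pulsing percepts) and ``depth`` the modulation depth
    in [0, 1] (weak to strong throbbing).  The modulator is the peak-preserving
    raised cosine ``m(t) = 1 - (depth/2)·(1 - cos(2π·rate·t))``.
    """

    model_config = {"frozen": True}

    rate_hz: float = Field(gt=0.0, le=20.0)
    depth: float = Field(ge=0.0, le=1.0)

    @classmethod
    def from_labels(cls, speed: str = "slow", strength: str = "weakly") -> "AMSpec":
        """Map the interface labels (slow/fast, weakly/strongly) to parameters."""
        rates = {"slow": 0.5, "medium": 3.0, "fast": 8.0}
        depths = {"weakly": 0.1, "medium": 0.5, "strongly": 1.0}
        return cls(rate_hz=rates[speed], depth=depths[strength])


class ToneComponent(BaseModel):
    """A pure tone at a fixed frequency and level."""

    model_config = {"frozen": True}

    frequency_hz: float = Field(ge=1.0, le=MAX_FREQUENCY_HZ)
    level_db_spl: float = Field(ge=0.0, le=120.0)
    am: Optional[AMSpec] = None


class NoiseComponent(BaseModel):
    """Band-limited white noise between two band edges.

    ``f_avg_hz`` — the arithmetic mean of the band edges — is the conventional
    single-number centre frequency reported for a matched noise band.
    """

    model_config = {"frozen": True}

    band_low_hz: float = Field(gt=0.0)
    band_high_hz: float = Field(gt=0.0, le=MAX_FREQUENCY_HZ)
    level_db_spl: float = Field(ge=0.0, le=120.0)
    am: Optional[AMSpec] = None

    @model_validator(mode="after")
    def _check_band(self) -> "NoiseComponent":
        if not self.band_low_hz < self.band_high_hz:
            raise ValueError(
                f"band_low_hz ({self.band_low_hz}) must be below "
                f"band_high_hz ({self.band_high_hz})"
            )
        return self

    @property
    def f_avg_hz(self) -> float:
        return 0.5 * (self.band_low_hz + self.band_high_hz)

    @property
    def bandwidth_octaves(self) -> float:
        return math.log2(self.band_high_hz / self.band_low_hz)


Component = Union[ToneComponent, NoiseComponent]


def component_frequency(component: Component) -> float:
    """Representative frequency of a component (tone frequency or F_avg)."""
    if isinstance(component, ToneComponent):
        return component.frequency_hz
    return component.f_avg_hz


class TinnitusModel(BaseModel):
    """A tinnitus percept/match: any number of tones and noises plus routing."""

    model_config = {"frozen": True}

    tones: tuple[ToneComponent, ...] = ()
    noises: tuple[NoiseComponent, ...] = ()
    ear: Ear = Ear.both

    @model_validator(mode="after")
    def _check_nonempty(self) -> "TinnitusModel":
        if not self.tones and not self.noises:
            raise ValueError("a TinnitusModel needs at least one component")
        return self

    @property
    def components(self) -> tuple[Component, ...]:
        return tuple(self.tones) + tuple(self.noises)

    @property
    def dominant(self) -> Component:
        """The loudest component (ties broken toward tones, then list order)."""
        comps = sorted(
            self.components,
            key=lambda c: (c.level_db_spl, isinstance(c, ToneComponent)),
        )
        return comps[-1]


class RenderConfig(BaseModel):
    """Rendering parameters.

    ``calibration_offset_db`` defines the digital SPL convention: a full-scale
    sinusoid (peak 1.0) represents this many dB SPL.  All component levels are
    interpreted against it.
    """

    model_config = {"frozen": True}

    sample_rate_hz: Literal[44100] = SAMPLE_RATE_HZ
    duration_s: float = Field(default=3.0, gt=0.0)
    bit_depth: Literal[16] = 16
    calibration_offset_db: float = 100.0
    rng_seed: int = 0

    @property
    def n_samples(self) -> int:
        return round(self.duration_s * self.sample_rate_hz)
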