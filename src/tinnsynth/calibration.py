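"""Audiometric scales and the audiometer stimulus model.

Three level scales are used throughout:

* **dB SPL** — sound pressure level re 20 µPa (the synthesizer's native scale).
* **dB HL** — hearing level: SPL minus the transducer-specific normal-hearing
  reference (RETSPL) at each audiometric frequency.
* **dB SL** — sensation level: level above the individual listener's own
  threshold at that frequency.

All conversions are affine lookups, so composed round-trips are exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .models import Ear, NoiseComponent

#: RETSPL for supra-aural audiometric earphones (dB SPL at 0 dB HL).
DEFAULT_RETSPL = {
    125.0: 45.0,
    250.0: 25.5,
    500.0: 11.5,
    750.0: 8.0,
    1000.0: 7.0,
    1500.0: 6.5,
    2000.0: 9.0,
    3000.0: 10.0,
    4000.0: 9.5,
    6000.0: 15.5,
    8000.0: 13.0,
}

AUDIOMETER_FREQUENCIES_HZ = (
    125.0, 250.0, 500.0, 750.0, 1000.0, 1500.0,
    2000.0, 3000.0, 4000.0, 6000.0, 8000.0,
)


@dataclass(frozen=True)
class RetsplTable:
    """frequency -> dB SPL offset of audiometric zero for one transducer."""

    offsets: dict[float, float] = field(default_factory=lambda: dict(DEFAULT_RETSPL))

    def offset(self, frequency_hz: float) -> float:
        try:
            return self.offsets[float(frequency_hz)]
        except KeyError:
            raise KeyError(
                f"no RETSPL offset for {frequency_hz} Hz; known frequencies: "
                f"{sorted(self.offsets)}"
            ) from None

    @classmethod
    def from_csv(cls, path: str | Path) -> "RetsplTable":
        df = pd.read_csv(path)
        return cls(offsets={float(f): float(o) for f, o in zip(df["frequency_hz"], df["offset_db"])})


@dataclass(frozen=True)
class AudiometerSpec:
    """The fixed stimulus vocabulary of a diagnostic audiometer."""

    frequencies_hz: tuple[float, ...] = AUDIOMETER_FREQUENCIES_HZ
    level_step_db: int = 5
    max_level_db_hl: float = 110.0

    def __post_init__(self):
        if self.level_step_db not in (1, 5):
            raise ValueError("level_step_db must be 1 or 5")

    def quantize_level(self, level_db: float) -> float:
        """Snap a level onto the audiometer's step grid."""
        return round(level_db / self.level_step_db) * self.level_step_db

    @property
    def octave_frequencies_hz(self) -> tuple[float, ...]:
        return tuple(f for f in self.frequencies_hz
                     if any(abs(f - 125.0 * 2**k) < 1e-9 for k in range(8)))


@dataclass(frozen=True)
class Audiogram:
    """Per-ear hearing thresholds in dB HL at audiometer frequencies."""

    thresholds: dict[Ear, dict[float, float]]

    def __post_init__(self):
        for ear, table in self.thresholds.items():
            if not table:
                raise ValueError(f"empty audiogram for ear {ear}")
            for f, thr in table.items():
                if not -10.0 <= thr <= 120.0:
                    raise ValueError(f"threshold {thr} dB HL at {f} Hz out of range")

    @classmethod
    def flat(cls, threshold_db_hl: float = 10.0,
             frequencies_hz: tuple[float, ...] = AUDIOMETER_FREQUENCIES_HZ) -> "Audiogram":
        table = {float(f): float(threshold_db_hl) for f in frequencies_hz}
        return cls(thresholds={Ear.left: dict(table), Ear.right: dict(table)})

    def ear_table(self, ear: Ear) -> dict[float, float]:
        if ear == Ear.both:
            raise ValueError("pick a concrete ear (left or right)")
        try:
            return self.thresholds[ear]
        except KeyError:
            raise KeyError(f"audiogram has no thresholds for ear {ear.value}") from None

    def threshold_hl(self, frequency_hz: float, ear: Ear) -> float:
        """Threshold in dB HL, linearly interpolated over log2(frequency)."""
        table = self.ear_table(ear)
        freqs = sorted(table)
        f = float(frequency_hz)
        if f in table:
            return table[f]
        if f <= freqs[0]:
            return table[freqs[0]]
        if f >= freqs[-1]:
            return table[freqs[-1]]
        for lo, hi in zip(freqs, freqs[1:]):
            if lo < f < hi:
                w = (math.log2(f) - math.log2(lo)) / (math.log2(hi) - math.log2(lo))
                return (1 - w) * table[lo] + w * table[hi]
        raise AssertionError("unreachable")

    @classmethod
    def from_csv(cls, path: str | Path) -> "Audiogram":
        df = pd.read_csv(path)
        thresholds: dict[Ear, dict[float, float]] = {}
        for _, row in df.iterrows():
            ear = Ear(row["ear"])
            thresholds.setdefault(ear, {})[float(row["frequency_hz"])] = float(
                row["threshold_db_hl"]
            )
        return cls(thresholds=thresholds)

    def to_csv(self, path: str | Path) -> None:
        rows = [
            {"ear": ear.value, "frequency_hz": f, "threshold_db_hl": thr}
            for ear, table in self.thresholds.items()
            for f, thr in sorted(table.items())
        ]
        pd.DataFrame(rows).to_csv(path, index=False)


def hl_to_spl(frequency_hz: float, level_db_hl: float,
              retspl: RetsplTable | None = None) -> float:
    """dB HL -> dB SPL via the RETSPL offset at that frequency."""
    retspl = retspl or RetsplTable()
    return level_db_hl + retspl.offset(frequency_hz)


def spl_to_hl(frequency_hz: float, level_db_spl: float,
              retspl: RetsplTable | None = None) -> float:
    """Inverse of :func:`hl_to_spl` (exact round trip)."""
    retspl = retspl or RetsplTable()
    return level_db_spl - retspl.offset(frequency_hz)


def threshold_spl(frequency_hz: float, audiogram: Audiogram, ear: Ear,
                  retspl: RetsplTable | None = None) -> float:
    """The listener's threshold at a frequency, in dB SPL.

    At non-audiometric frequencies the per-frequency threshold *SPL* values
    are interpolated linearly over log2(frequency), which sidesteps the need
    for RETSPL offsets off the audiometric grid.
    """
    retspl = retspl or RetsplTable()
    table = audiogram.ear_table(ear)
    spl_table = {f: hl_to_spl(f, thr, retspl) for f, thr in table.items()}
    freqs = sorted(spl_table)
    f = float(frequency_hz)
    if f in spl_table:
        return spl_table[f]
    if f <= freqs[0]:
        return spl_table[freqs[0]]
    if f >= freqs[-1]:
        return spl_table[freqs[-1]]
    for lo, hi in zip(freqs, freqs[1:]):
        if lo < f < hi:
            w = (math.log2(f) - math.log2(lo)) / (math.log2(hi) - math.log2(lo))
            return (1 - w) * spl_table[lo] + w * spl_table[hi]
    raise AssertionError("unreachable")


def sl_to_spl(frequency_hz: float, level_db_sl: float, audiogram: Audiogram,
              ear: Ear, retspl: RetsplTable | None = None) -> float:
    """dB SL -> dB SPL: sensation level above the listener's own threshold."""
    return threshold_spl(frequency_hz, audiogram, ear, retspl) + level_db_sl


def spl_to_sl(frequency_hz: float, level_db_spl: float, audiogram: Audiogram,
              ear: Ear, retspl: RetsplTable | None = None) -> float:
    """Inverse of :func:`sl_to_spl`."""
    return level_db_spl - threshold_spl(frequency_hz, audiogram, ear, retspl)


def narrowband_masker(center_hz: float, level_db_spl: float = 60.0,
                      spec: AudiometerSpec | None = None) -> NoiseComponent:
    """The audiometric 1/3-octave narrowband masking noise at a set frequency.

    Band edges are geometric: ``center·2^(±1/6)``.
    """
    spec = spec or AudiometerSpec()
    if float(center_hz) not in spec.frequencies_hz:
        raise ValueError(
            f"{center_hz} Hz is not an audiometer frequency {spec.frequencies_hz}"
        )
    return NoiseComponent(
        band_low_hz=center_hz * 2.0 ** (-1.0 / 6.0),
        band_high_hz=center_hz * 2.0 ** (1.0 / 6.0),
        level_db_spl=level_db_spl,
    )
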