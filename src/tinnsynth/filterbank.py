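"""1/8-octave FIR filterbank used as a multi-band equalizer.

The band is split into 62 contiguous 1/8-octave sub-bands.  Sixty-two
1/8-octave bands span 7.75 octaves; the bank places band centres at
``100·2^(k/8)`` Hz for k = 0..61 (~100 Hz to ~19.7 kHz), which covers the
audiometric and tinnitus-relevant range inside the 44.1 kHz Nyquist limit.

Each band is a linear-phase windowed-sinc (Hamming) band-pass whose -6 dB
cutoffs sit exactly on the band edges, with enough taps that the transition
band stays within 1/16 octave.  Because every filter is linear-phase and is
applied centred (zero overall delay), adjacent bands cross over coherently at
amplitude 0.5 each: the coherent sum of any run of bands is flat over its
union, and the magnitude responses of all 62 bands sum to ~1 across coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import signal

from .models import RenderConfig

N_BANDS = 62
EDGE_RATIO = 2.0 ** (1.0 / 8.0)
BASE_CENTER_HZ = 100.0
#: taps ~ TAP_FACTOR · fs / (1/16-octave transition width at the lower edge)
_TAP_FACTOR = 3.5


@dataclass(frozen=True)
class Band:
    low_edge_hz: float
    high_edge_hz: float
    fir_coefficients: np.ndarray

    @property
    def center_hz(self) -> float:
        return float(np.sqrt(self.low_edge_hz * self.high_edge_hz))


@dataclass(frozen=True)
class Filterbank:
    bands: tuple[Band, ...]
    sample_rate_hz: int

    @property
    def n_bands(self) -> int:
        return len(self.bands)

    @property
    def coverage_hz(self) -> tuple[float, float]:
        return self.bands[0].low_edge_hz, self.bands[-1].high_edge_hz

    def band_indices_overlapping(self, low_hz: float, high_hz: float) -> list[int]:
        """Indices of bands whose interval intersects [low_hz, high_hz]."""
        return [
            k
            for k, b in enumerate(self.bands)
            if b.low_edge_hz < high_hz and b.high_edge_hz > low_hz
        ]

    def combined_coefficients(self, indices: list[int]) -> np.ndarray:
        """Centre-aligned coherent sum of the selected band filters.

        All filters are odd-length linear-phase; summing them centre-aligned
        yields a single zero-phase-appliable FIR whose response is the sum of
        the individual band responses (flat over a contiguous run of bands).
        """
        if not indices:
            raise ValueError("no bands selected")
        n = max(len(self.bands[k].fir_coefficients) for k in indices)
        out = np.zeros(n)
        c = n // 2
        for k in indices:
            h = self.bands[k].fir_coefficients
            half = len(h) // 2
            out[c - half : c + half + 1] += h
        return out

    def magnitude_responses(self, nfft: int = 2**18) -> tuple[np.ndarray, np.ndarray]:
        """(freqs, |H|) with |H| of shape (n_bands, nfft//2 + 1)."""
        freqs = np.fft.rfftfreq(nfft, 1.0 / self.sample_rate_hz)
        mags = np.array(
            [np.abs(np.fft.rfft(b.fir_coefficients, nfft)) for b in self.bands]
        )
        return freqs, mags


def _num_taps(low_edge_hz: float, fs: float) -> int:
    transition_hz = low_edge_hz * (2 ** (1 / 32) - 2 ** (-1 / 32))
    n = int(np.ceil(_TAP_FACTOR * fs / transition_hz))
    return n | 1  # odd length -> type-I linear phase, integer group delay


def design_filterbank(config: RenderConfig | None = None) -> Filterbank:
    """Design the fixed 62-band 1/8-octave FIR filterbank."""
    config = config or RenderConfig()
    fs = config.sample_rate_hz
    bands = []
    for k in range(N_BANDS):
        center = BASE_CENTER_HZ * 2.0 ** (k / 8.0)
        low = center * 2.0 ** (-1.0 / 16.0)
        high = center * 2.0 ** (1.0 / 16.0)
        taps = signal.firwin(
            _num_taps(low, fs), [low, high], pass_zero=False, window="hamming", fs=fs
        )
        bands.append(Band(low_edge_hz=low, high_edge_hz=high, fir_coefficients=taps))
    return Filterbank(bands=tuple(bands), sample_rate_hz=fs)


@lru_cache(maxsize=1)
def default_filterbank() -> Filterbank:
    """The default-design bank, cached (design is deterministic)."""
    return design_filterbank(RenderConfig())
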