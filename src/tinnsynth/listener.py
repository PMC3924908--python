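"""A seedable simulated patient for exercising the matching procedures.

The virtual listener holds a ground-truth percept (a :class:`TinnitusModel`)
plus psychometric response parameters, and answers the queries the procedures
need: pitch comparisons, loudness balances, audibility-under-masking
judgements, preference between two candidate sounds, and 0-10 similarity
ratings.  All stochastic behaviour (decision noise, lapses, residual
inhibition) comes from a single seeded generator, so identical seeds replay
identical response sequences.

The response model is deliberately simple — its job is ordinal correctness
(closer stimuli are preferred, louder maskers mask), not human realism:

* pitch decisions: sign of ``log2(stimulus/percept) + N(0, pitch_jnd)``;
* loudness decisions: level difference plus ``N(0, level_jnd)``, with an
  "equal" band of half a JND (at least ±0.5 dB, half the finest 1 dB step);
* masking: energetic rule — the percept is inaudible when the masker's
  effective level inside the percept's 1/3-octave neighbourhood reaches the
  percept level minus a 10 dB margin (tinnitus typically masks within
  ~10 dB SL of its matched loudness);
* similarity: ``rating = round(10·exp(-slope·cost))`` where the cost sums
  octave distance (scale 1 octave), level distance (scale 20 dB) and a unit
  penalty per character mismatch or unmatched component.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .calibration import Audiogram, RetsplTable, threshold_spl
from .models import (
    Component,
    Ear,
    NoiseComponent,
    TinnitusModel,
    ToneComponent,
    component_frequency,
)

#: cost scales of the similarity model
SIGMA_F_OCTAVES = 1.0
SIGMA_L_DB = 20.0
CHARACTER_PENALTY = 1.0
UNMATCHED_PENALTY = 1.0
#: a noise percept wider than this has no dominant band to pitch-compare
MAX_PITCH_BANDWIDTH_OCTAVES = 3.0


class PitchComparison(Enum):
    stimulus_higher = "stimulus_higher"
    stimulus_lower = "stimulus_lower"


class LoudnessComparison(Enum):
    stimulus_louder = "stimulus_louder"
    stimulus_softer = "stimulus_softer"
    equal = "equal"


class NoDominantBandError(ValueError):
    """The percept is broadband noise; pitch comparison is undefined."""


@dataclass(frozen=True)
class SimilarityBreakdown:
    frequency_distance_octaves: float
    level_distance_db: float
    character_mismatch: int
    rating_0_10: int


def _component_kind(c: Component) -> str:
    return "tone" if isinstance(c, ToneComponent) else "noise"


def _greedy_pairs(
    percept: tuple[Component, ...], candidate: tuple[Component, ...]
) -> tuple[list[tuple[Component, Component]], int]:
    """Greedily pair percept and candidate components by octave distance.

    Returns the matched pairs and the number of unmatched components
    (surplus on either side).
    """
    remaining = list(candidate)
    pairs = []
    for p in sorted(percept, key=lambda c: -c.level_db_spl):
        if not remaining:
            break
        best = min(
            remaining,
            key=lambda c: abs(
                math.log2(component_frequency(c) / component_frequency(p))
            ),
        )
        remaining.remove(best)
        pairs.append((p, best))
    unmatched = abs(len(percept) - len(candidate))
    return pairs, unmatched


@dataclass
class VirtualListener:
    """Ground-truth percept plus psychometric response parameters."""

    percept: TinnitusModel
    audiogram: Audiogram
    pitch_jnd_octaves: float = 0.0
    level_jnd_db: float = 0.0
    lapse_rate: float = 0.0
    rating_slope: float = 1.0
    masking_margin_db: float = 10.0
    #: residual-inhibition response stub: percentage reduction ~ N(mean, sd)
    ri_reduction_mean: float = 0.0
    ri_reduction_sd: float = 0.0
    #: direct-manipulation placement accuracy on the synthesizer interface
    placement_octaves: float = 0.5
    placement_db: float = 8.0
    retspl: RetsplTable = field(default_factory=RetsplTable)
    rng_seed: int = 0

    def __post_init__(self):
        if self.pitch_jnd_octaves < 0 or self.level_jnd_db < 0:
            raise ValueError("JND parameters must be non-negative")
        if not 0.0 <= self.lapse_rate <= 0.2:
            raise ValueError("lapse_rate must lie in [0, 0.2]")
        self.rng = np.random.default_rng(self.rng_seed)

    # -- percept geometry ---------------------------------------------------

    def _heard_in(self, ear: Ear) -> tuple[Component, ...]:
        if ear == Ear.both or self.percept.ear == Ear.both or ear == self.percept.ear:
            return self.percept.components
        return ()

    def dominant_component(self, ear: Ear = Ear.both) -> Component | None:
        comps = self._heard_in(ear)
        if not comps:
            return None
        return max(comps, key=lambda c: (c.level_db_spl, isinstance(c, ToneComponent)))

    def procedure_ear(self) -> Ear:
        """The ear a monaural procedure should address (better ear if both)."""
        if self.percept.ear != Ear.both:
            return self.percept.ear
        f = component_frequency(self.percept.dominant)
        thr = {
            e: threshold_spl(f, self.audiogram, e, self.retspl)
            for e in (Ear.left, Ear.right)
        }
        return min((Ear.right, Ear.left), key=lambda e: thr[e])

    def _dominant_frequency(self) -> float:
        dom = self.percept.dominant
        if isinstance(dom, NoiseComponent) and (
            dom.bandwidth_octaves > MAX_PITCH_BANDWIDTH_OCTAVES
        ):
            raise NoDominantBandError(
                "broadband noise percept has no dominant band; "
                "use the character-check flow instead of pitch comparison"
            )
        return component_frequency(dom)

    # -- elementary judgements ---------------------------------------------

    def _lapse(self) -> bool:
        return self.lapse_rate > 0.0 and self.rng.random() < self.lapse_rate

    def compare_pitch(self, stimulus_hz: float) -> PitchComparison:
        """Is the presented tone higher or lower than the tinnitus?

        Ties (zero perceived distance) break deterministically to
        ``stimulus_higher``.
        """
        f_p = self._dominant_frequency()
        if self._lapse():
            return self.rng.choice(list(PitchComparison))
        x = math.log2(stimulus_hz / f_p)
        if self.pitch_jnd_octaves > 0.0:
            x += self.rng.normal(0.0, self.pitch_jnd_octaves)
        return PitchComparison.stimulus_higher if x >= 0 else PitchComparison.stimulus_lower

    def closer_of_two(self, f1_hz: float, f2_hz: float) -> float:
        """2AFC: which of two tone frequencies is closer to the tinnitus pitch?

        Ties break to the first alternative.
        """
        f_p = self._dominant_frequency()
        if self._lapse():
            return float(self.rng.choice([f1_hz, f2_hz]))
        d1 = math.log2(f1_hz / f_p)
        d2 = math.log2(f2_hz / f_p)
        if self.pitch_jnd_octaves > 0.0:
            d1 += self.rng.normal(0.0, self.pitch_jnd_octaves)
            d2 += self.rng.normal(0.0, self.pitch_jnd_octaves)
        return f1_hz if abs(d1) <= abs(d2) else f2_hz

    def loudness_balanced(
        self, stimulus: Component, ear: Ear | None = None
    ) -> LoudnessComparison:
        """Compare the stimulus loudness against the dominant percept.

        An inaudible stimulus (below the audiogram threshold at its
        frequency) always reads as softer.
        """
        ear = ear or self.procedure_ear()
        thr = threshold_spl(
            component_frequency(stimulus), self.audiogram, ear, self.retspl
        )
        if stimulus.level_db_spl < thr:
            return LoudnessComparison.stimulus_softer
        dom = self.dominant_component(ear)
        if dom is None:
            return LoudnessComparison.stimulus_louder
        diff = stimulus.level_db_spl - dom.level_db_spl
        if self._lapse():
            return self.rng.choice(list(LoudnessComparison))
        if self.level_jnd_db > 0.0:
            diff += self.rng.normal(0.0, self.level_jnd_db)
        eq_band = max(self.level_jnd_db / 2.0, 0.5)
        if abs(diff) <= eq_band:
            return LoudnessComparison.equal
        return (
            LoudnessComparison.stimulus_louder
            if diff > 0
            else LoudnessComparison.stimulus_softer
        )

    # -- masking ------------------------------------------------------------

    def masked_at(self, effective_level_db: float, ear: Ear = Ear.both) -> bool:
        """Is the percept in this ear inaudible under the given effective
        masker level (level within the percept's 1/3-octave neighbourhood)?"""
        dom = self.dominant_component(ear)
        if dom is None:
            return True
        return effective_level_db >= dom.level_db_spl - self.masking_margin_db

    def effective_masker_level(
        self, masker: NoiseComponent, ear: Ear = Ear.both
    ) -> float:
        """The masker's level restricted to the percept's 1/3-octave
        neighbourhood, assuming a spectrally flat masker band."""
        dom = self.dominant_component(ear)
        if dom is None:
            return masker.level_db_spl
        f = component_frequency(dom)
        n_lo, n_hi = f * 2 ** (-1 / 6), f * 2 ** (1 / 6)
        overlap = min(masker.band_high_hz, n_hi) - max(masker.band_low_hz, n_lo)
        if overlap <= 0:
            return -math.inf
        bw = masker.band_high_hz - masker.band_low_hz
        return masker.level_db_spl - 10.0 * math.log10(bw / min(overlap, bw))

    def is_tinnitus_audible(
        self, masker: NoiseComponent, ear: Ear = Ear.both
    ) -> bool:
        """Energetic masking rule for the dominant percept component."""
        if self.dominant_component(ear) is None:
            return False
        return not self.masked_at(self.effective_masker_level(masker, ear), ear)

    # -- similarity ---------------------------------------------------------

    def _similarity_cost(self, candidate: TinnitusModel) -> tuple[float, float, float, int]:
        pairs, unmatched = _greedy_pairs(self.percept.components, candidate.components)
        cost = unmatched * UNMATCHED_PENALTY
        mismatches = 0
        d_f_dom = d_l_dom = 0.0
        dom = self.percept.dominant
        for p, c in pairs:
            d_f = abs(math.log2(component_frequency(c) / component_frequency(p)))
            d_l = abs(c.level_db_spl - p.level_db_spl)
            mism = int(_component_kind(p) != _component_kind(c))
            cost += d_f / SIGMA_F_OCTAVES + d_l / SIGMA_L_DB + mism * CHARACTER_PENALTY
            mismatches += mism
            if p is dom:
                d_f_dom, d_l_dom = d_f, d_l
        return cost, d_f_dom, d_l_dom, mismatches

    def continuous_similarity(self, candidate: TinnitusModel) -> float:
        """Internal continuous goodness score (higher is better, max 0)."""
        return -self._similarity_cost(candidate)[0]

    def rate_similarity(self, candidate: TinnitusModel) -> SimilarityBreakdown:
        """The 0-10 resemblance rating the patient reports for a candidate."""
        cost, d_f, d_l, mism = self._similarity_cost(candidate)
        rating = int(round(10.0 * math.exp(-self.rating_slope * cost)))
        return SimilarityBreakdown(
            frequency_distance_octaves=d_f,
            level_distance_db=d_l,
            character_mismatch=mism,
            rating_0_10=max(0, min(10, rating)),
        )

    def prefer(self, candidate: TinnitusModel, incumbent: TinnitusModel) -> bool:
        """Does the candidate sound closer to the tinnitus than the incumbent?

        Ties keep the incumbent.
        """
        if self._lapse():
            return bool(self.rng.random() < 0.5)
        sd = (
            self.pitch_jnd_octaves / SIGMA_F_OCTAVES
            + self.level_jnd_db / SIGMA_L_DB
        )
        a = self.continuous_similarity(candidate)
        b = self.continuous_similarity(incumbent)
        if sd > 0.0:
            a += self.rng.normal(0.0, sd)
            b += self.rng.normal(0.0, sd)
        return a > b

    # -- residual inhibition stub --------------------------------------------

    def ri_response(self) -> float:
        """Percentage reduction of the percept after masking exposure."""
        if self.ri_reduction_sd > 0.0:
            value = self.rng.normal(self.ri_reduction_mean, self.ri_reduction_sd)
        else:
            value = self.ri_reduction_mean
        return float(min(100.0, max(0.0, value)))

    # -- synthesizer interface motor model ------------------------------------

    def place_near(self, target: Component) -> tuple[float, float]:
        """Where the patient drops an icon intended to match ``target``.

        The frequency and level axes are visible on the interface, so
        placement lands within ``placement_octaves`` / ``placement_db`` of
        the intended percept component.
        """
        f = component_frequency(target) * 2.0 ** self.rng.uniform(
            -self.placement_octaves, self.placement_octaves
        )
        level = target.level_db_spl + self.rng.uniform(
            -self.placement_db, self.placement_db
        )
        return float(f), float(min(120.0, max(0.0, level)))

    def initial_placement(self) -> tuple[float, float]:
        """First placement: aimed at the dominant percept component."""
        return self.place_near(self.percept.dominant)


def make_tonal_population(
    n: int,
    seed: int,
    frequency_range_hz: tuple[float, float] = (250.0, 8000.0),
    sl_range_db: tuple[float, float] = (5.0, 25.0),
    threshold_db_hl: float = 10.0,
    **listener_kwargs,
) -> list[VirtualListener]:
    """N seeded listeners with single-tone percepts.

    Percept frequencies are log-uniform over ``frequency_range_hz``; percept
    levels sit a uniform 5-25 dB SL above a flat audiogram (matched tinnitus
    loudness is typically within a couple of tens of dB SL of threshold).
    """
    master = np.random.default_rng(seed)
    audiogram = Audiogram.flat(threshold_db_hl)
    listeners = []
    for i in range(n):
        f = float(
            np.exp(master.uniform(*np.log(np.asarray(frequency_range_hz))))
        )
        sl = float(master.uniform(*sl_range_db))
        level = threshold_spl(f, audiogram, Ear.right) + sl
        percept = TinnitusModel(
            tones=(ToneComponent(frequency_hz=f, level_db_spl=level),),
            ear=Ear.both,
        )
        listeners.append(
            VirtualListener(
                percept=percept,
                audiogram=audiogram,
                rng_seed=int(master.integers(2**31)),
                **listener_kwargs,
            )
        )
    return listeners


def make_study_population(n: int, seed: int, **listener_kwargs) -> list[VirtualListener]:
    """A percept mix like the study group: mostly tonal, some narrow noise."""
    master = np.random.default_rng(seed)
    audiogram = Audiogram.flat(10.0)
    listeners = []
    for i in range(n):
        f = float(np.exp(master.uniform(np.log(250.0), np.log(8000.0))))
        sl = float(master.uniform(5.0, 25.0))
        level = threshold_spl(f, audiogram, Ear.right) + sl
        if i % 4 == 3:  # roughly the study's 4-in-14 noise-like percepts
            width = float(master.uniform(1 / 3, 1.5))  # octaves
            comp = NoiseComponent(
                band_low_hz=f * 2 ** (-width / 2),
                band_high_hz=min(f * 2 ** (width / 2), 20000.0),
                level_db_spl=level,
            )
            percept = TinnitusModel(noises=(comp,), ear=Ear.both)
        else:
            percept = TinnitusModel(
                tones=(ToneComponent(frequency_hz=f, level_db_spl=level),),
                ear=Ear.both,
            )
        listeners.append(
            VirtualListener(
                percept=percept,
                audiogram=audiogram,
                rng_seed=int(master.integers(2**31)),
                **listener_kwargs,
            )
        )
    return listeners
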