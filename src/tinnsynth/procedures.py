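"""Tinnitus measurement protocols driven by a virtual listener.

Implements the classic audiometric battery — octave-bracketing pitch
matching (2AFC), loudness matching by staircase, tone/noise character check,
minimum masking level (MML) and residual inhibition — plus the two-stage
comparison session:

* **Stage I** (audiometer): an examiner-mediated search over the fixed
  11-frequency vocabulary.  Pitch is matched first and loudness only
  afterwards (repeated loudness balancing at every pitch candidate is what
  makes the classic order slow), following the modified order used with the
  synthesizer study.
* **Stage II** (synthesizer): the patient drives a 2-D direct-manipulation
  interface; components are placed roughly right immediately and refined by
  coarse-to-fine self-adjustment (1/16-octave and 1 dB at the finest).

Durations are modelled as presentation counts times a configurable
seconds-per-presentation constant: each audiometer stimulus is one
presentation (a 2AFC pair costs two); on the synthesizer one continuous
adjustment sweep per refinement level counts as one settled audition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable

from .calibration import (
    Audiogram,
    AudiometerSpec,
    RetsplTable,
    narrowband_masker,
    sl_to_spl,
    threshold_spl,
)
from .filterbank import default_filterbank
from .listener import (
    LoudnessComparison,
    PitchComparison,
    VirtualListener,
    _greedy_pairs,
)
from .models import (
    Component,
    Ear,
    NoiseComponent,
    TinnitusModel,
    ToneComponent,
    component_frequency,
)

SECONDS_PER_PRESENTATION = 10.0
STAGE_I_PRESENTATION_CAP = 100
STAGE_II_MOVE_CAP = 500


class StimulusKind(Enum):
    tone = "tone"
    narrowband_noise = "narrowband_noise"
    broadband_noise = "broadband_noise"


@dataclass
class PitchMatchResult:
    matched_frequency_hz: float
    trajectory: list[tuple[float, str]]
    n_presentations: int
    converged: bool = True


@dataclass
class LoudnessMatchResult:
    level_db_sl: float
    level_db_spl: float
    trajectory: list[tuple[float, str]]
    n_presentations: int
    capped: bool = False


@dataclass
class CharacterCheckResult:
    kind: StimulusKind
    level_db_sl: float
    n_presentations: int


@dataclass
class MMLResult:
    mml_db: dict[Ear, float]
    binaural: bool
    steps: list[tuple[float, float, bool, bool]]
    masker: NoiseComponent
    capped: bool = False


@dataclass
class ResidualInhibitionResult:
    stimulus_level_db: float
    exposure_s: float
    reduction_percent: float


@dataclass
class SessionRecord:
    participant_id: int
    method: str  # "audiometer" | "synthesizer"
    matched_model: TinnitusModel
    similarity_0_10: int
    duration_min: float
    n_presentations: int
    flags: list[str] = field(default_factory=list)

    def to_row(self) -> dict:
        return {
            "participant_id": self.participant_id,
            "method": self.method,
            "similarity_0_10": self.similarity_0_10,
            "duration_min": self.duration_min,
            "n_presentations": self.n_presentations,
            "flags": ";".join(self.flags),
        }


# ---------------------------------------------------------------------------
# pitch matching
# ---------------------------------------------------------------------------

def pitch_match_octave(
    listener: VirtualListener,
    spec: AudiometerSpec | None = None,
    max_presentations: int = STAGE_I_PRESENTATION_CAP,
) -> PitchMatchResult:
    """Bracket the tinnitus pitch over octave frequencies, then refine.

    Starts at 1000 Hz and walks the octave ladder in the direction the
    listener indicates until the response reverses (or the ladder ends),
    which narrows the pitch to one octave.  The inter-octave audiometer
    frequency inside the bracket is then pitted against both octave
    endpoints in 2AFC trials; conflicting endpoint wins are resolved by a
    best-of-three forced choice.
    """
    spec = spec or AudiometerSpec()
    octaves = sorted(spec.octave_frequencies_hz)
    trajectory: list[tuple[float, str]] = []
    n = 0

    def present(f: float) -> PitchComparison:
        nonlocal n
        resp = listener.compare_pitch(f)
        trajectory.append((f, resp.value))
        n += 1
        return resp

    def choose(f1: float, f2: float) -> float:
        nonlocal n
        winner = listener.closer_of_two(f1, f2)
        trajectory.append((f1, "chosen" if winner == f1 else "not_chosen"))
        trajectory.append((f2, "chosen" if winner == f2 else "not_chosen"))
        n += 2
        return winner

    idx = octaves.index(1000.0)
    first = present(octaves[idx])
    # stimulus_higher: the tone sits above the tinnitus -> walk downwards
    direction = -1 if first == PitchComparison.stimulus_higher else 1
    lo = hi = octaves[idx]
    converged = True
    while True:
        nxt = idx + direction
        if nxt < 0 or nxt >= len(octaves):
            # ladder exhausted: percept beyond the vocabulary edge
            other = idx - direction
            lo, hi = sorted((octaves[idx], octaves[other]))
            break
        resp = present(octaves[nxt])
        # keep walking while the tone stays on the same side of the tinnitus
        keep_going = (resp == PitchComparison.stimulus_lower) == (direction == 1)
        if not keep_going:
            lo, hi = sorted((octaves[idx], octaves[nxt]))
            break
        idx = nxt
        if n >= max_presentations:
            converged = False
            break

    mids = [f for f in spec.frequencies_hz if lo < f < hi]
    if not converged:
        matched = octaves[idx]
    elif mids:
        mid = mids[0]
        w1 = choose(lo, mid)
        w2 = choose(mid, hi)
        if w1 == mid and w2 == mid:
            matched = mid
        elif w1 == lo and w2 == mid:
            matched = lo
        elif w1 == mid and w2 == hi:
            matched = hi
        else:  # lo and hi each beat the middle: conflict, best of three
            wins = [choose(lo, hi) for _ in range(3)]
            matched = max(set(wins), key=wins.count)
    else:
        matched = choose(lo, hi)

    return PitchMatchResult(
        matched_frequency_hz=matched,
        trajectory=trajectory,
        n_presentations=n,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# loudness matching
# ---------------------------------------------------------------------------

def _starting_sl(threshold_db_hl: float, coarse_step_db: int) -> float:
    # 10-20 dB SL with normal thresholds, 5-10 dB SL with hearing loss
    target = 15.0 if threshold_db_hl <= 20.0 else 7.5
    return round(target / coarse_step_db) * coarse_step_db


def loudness_match(
    listener: VirtualListener,
    frequency_hz: float,
    audiogram: Audiogram | None = None,
    ear: Ear | None = None,
    retspl: RetsplTable | None = None,
    coarse_step_db: int = 5,
    fine_step_db: int = 1,
    start_sl: float | None = None,
    stimulus_factory: Callable[[float], Component] | None = None,
    stop_after_first_reversal: bool = False,
    max_presentations: int = STAGE_I_PRESENTATION_CAP,
) -> LoudnessMatchResult:
    """Staircase loudness balance at a fixed frequency.

    Starts at 15 dB SL (7.5 dB SL when the threshold shows hearing loss,
    i.e. exceeds 20 dB HL), moves in audiometer 5 dB steps until the first
    reversal, then in 1 dB steps until the listener reports the stimulus
    equal in loudness to the tinnitus.
    """
    audiogram = audiogram or listener.audiogram
    ear = ear or listener.procedure_ear()
    retspl = retspl or listener.retspl
    thr_hl = audiogram.threshold_hl(frequency_hz, ear)
    thr_spl = threshold_spl(frequency_hz, audiogram, ear, retspl)
    sl = _starting_sl(thr_hl, coarse_step_db) if start_sl is None else start_sl
    make = stimulus_factory or (
        lambda spl: ToneComponent(frequency_hz=frequency_hz, level_db_spl=spl)
    )

    trajectory: list[tuple[float, str]] = []
    step = float(coarse_step_db)
    prev_dir = 0
    capped = False
    n = 0
    while True:
        spl = min(120.0, max(0.0, thr_spl + sl))
        resp = listener.loudness_balanced(make(spl), ear)
        trajectory.append((sl, resp.value))
        n += 1
        if resp == LoudnessComparison.equal:
            break
        if n >= max_presentations or thr_spl + sl > 120.0:
            capped = True
            break
        direction = 1 if resp == LoudnessComparison.stimulus_softer else -1
        if prev_dir != 0 and direction != prev_dir:
            if stop_after_first_reversal:
                break  # "close enough": a coarse preset, not a final match
            step = float(fine_step_db)
        prev_dir = direction
        sl += direction * step

    return LoudnessMatchResult(
        level_db_sl=sl,
        level_db_spl=thr_spl + sl,
        trajectory=trajectory,
        n_presentations=n,
        capped=capped,
    )


# ---------------------------------------------------------------------------
# character check
# ---------------------------------------------------------------------------

def _broadband_component(level_db_spl: float) -> NoiseComponent:
    lo, hi = default_filterbank().coverage_hz
    return NoiseComponent(band_low_hz=lo, band_high_hz=hi, level_db_spl=level_db_spl)


def character_check(
    listener: VirtualListener,
    matched_frequency_hz: float,
    matched_level_db_sl: float,
    audiogram: Audiogram | None = None,
    ear: Ear | None = None,
    retspl: RetsplTable | None = None,
    spec: AudiometerSpec | None = None,
    do_rematch: bool = True,
) -> CharacterCheckResult:
    """Does the tinnitus sound more like a tone or like noise?

    Presents the matched-pitch tone against the narrowband masker noise at
    that frequency; only if the noise is preferred does the comparison widen
    to broadband.  The winner's loudness is re-matched in 1 dB steps.
    """
    audiogram = audiogram or listener.audiogram
    ear = ear or listener.procedure_ear()
    retspl = retspl or listener.retspl
    spec = spec or AudiometerSpec()
    spl = min(
        120.0,
        max(0.0, sl_to_spl(matched_frequency_hz, matched_level_db_sl, audiogram, ear, retspl)),
    )
    route = listener.percept.ear
    tone = TinnitusModel(
        tones=(ToneComponent(frequency_hz=matched_frequency_hz, level_db_spl=spl),),
        ear=route,
    )
    nb_comp = narrowband_masker(matched_frequency_hz, spl, spec)
    nb = TinnitusModel(noises=(nb_comp,), ear=route)
    n = 2
    kind = StimulusKind.tone
    winner_factory: Callable[[float], Component] = lambda s: ToneComponent(
        frequency_hz=matched_frequency_hz, level_db_spl=s
    )
    if listener.prefer(nb, tone):  # ties keep the tone: the tone result is final
        bb = TinnitusModel(noises=(_broadband_component(spl),), ear=route)
        n += 2
        if listener.prefer(bb, nb):
            kind = StimulusKind.broadband_noise
            winner_factory = _broadband_component
        else:
            kind = StimulusKind.narrowband_noise
            winner_factory = lambda s: narrowband_masker(matched_frequency_hz, s, spec)

    level_sl = matched_level_db_sl
    if do_rematch:
        rematch = loudness_match(
            listener,
            matched_frequency_hz,
            audiogram,
            ear,
            retspl,
            coarse_step_db=1,
            fine_step_db=1,
            start_sl=matched_level_db_sl,
            stimulus_factory=winner_factory,
        )
        level_sl = rematch.level_db_sl
        n += rematch.n_presentations
    return CharacterCheckResult(kind=kind, level_db_sl=level_sl, n_presentations=n)


# ---------------------------------------------------------------------------
# minimum masking level & residual inhibition
# ---------------------------------------------------------------------------

def measure_mml(
    listener: VirtualListener,
    audiogram: Audiogram | None = None,
    retspl: RetsplTable | None = None,
    step_db: float = 1.0,
    max_level_db: float = 110.0,
) -> MMLResult:
    """Binaural broadband-noise minimum masking level.

    The noise starts at each ear's hearing threshold and rises in joint 1 dB
    increments; once one ear reports the tinnitus inaudible the level keeps
    rising contralaterally only.  Levels are tracked as the effective masker
    level within the dominant percept's 1/3-octave neighbourhood.
    """
    audiogram = audiogram or listener.audiogram
    retspl = retspl or listener.retspl
    dom = listener.percept.dominant
    f_dom = component_frequency(dom)
    ears = (Ear.left, Ear.right)
    level = {
        e: threshold_spl(
            component_frequency(listener.dominant_component(e) or dom),
            audiogram,
            e,
            retspl,
        )
        for e in ears
    }
    steps: list[tuple[float, float, bool, bool]] = []
    capped = False
    while True:
        masked = {e: listener.masked_at(level[e], e) for e in ears}
        steps.append((level[Ear.left], level[Ear.right], masked[Ear.left], masked[Ear.right]))
        if all(masked.values()):
            break
        if any(level[e] >= max_level_db for e in ears if not masked[e]):
            capped = True
            break
        for e in ears:
            if not masked[e]:
                level[e] += step_db

    # equivalent overall broadband level for the reported effective level
    lo, hi = default_filterbank().coverage_hz
    neigh_bw = f_dom * (2 ** (1 / 6) - 2 ** (-1 / 6))
    overall = max(level.values()) + 10.0 * math.log10((hi - lo) / neigh_bw)
    masker = NoiseComponent(
        band_low_hz=lo, band_high_hz=hi, level_db_spl=min(120.0, max(0.0, overall))
    )
    return MMLResult(mml_db=dict(level), binaural=True, steps=steps, masker=masker, capped=capped)


def residual_inhibition(
    listener: VirtualListener, mml: MMLResult
) -> ResidualInhibitionResult:
    """One-minute masking exposure at MML + 10 dB; reduction in percent."""
    return ResidualInhibitionResult(
        stimulus_level_db=max(mml.mml_db.values()) + 10.0,
        exposure_s=60.0,
        reduction_percent=listener.ri_response(),
    )


# ---------------------------------------------------------------------------
# the two-stage session
# ---------------------------------------------------------------------------

def run_stage_I(
    listener: VirtualListener,
    spec: AudiometerSpec | None = None,
    participant_id: int = 0,
    seconds_per_presentation: float = SECONDS_PER_PRESENTATION,
) -> SessionRecord:
    """Audiometer stage: preset loudness, pitch match, character check,
    final loudness match over the fixed stimulus vocabulary."""
    spec = spec or AudiometerSpec()
    ear = listener.procedure_ear()
    flags: list[str] = []
    n = 0

    # the examiner first sets the 1000 Hz tone near the tinnitus loudness
    preset = loudness_match(
        listener, 1000.0, ear=ear, coarse_step_db=5, fine_step_db=5,
        stop_after_first_reversal=True, max_presentations=8,
    )
    n += preset.n_presentations

    pitch = pitch_match_octave(listener, spec)
    n += pitch.n_presentations
    if not pitch.converged:
        flags.append("pitch_cap")

    char = character_check(
        listener, pitch.matched_frequency_hz, preset.level_db_sl,
        ear=ear, spec=spec, do_rematch=False,
    )
    n += char.n_presentations

    if char.kind == StimulusKind.tone:
        factory = lambda s: ToneComponent(
            frequency_hz=pitch.matched_frequency_hz, level_db_spl=s
        )
    elif char.kind == StimulusKind.narrowband_noise:
        factory = lambda s: narrowband_masker(pitch.matched_frequency_hz, s, spec)
    else:
        factory = _broadband_component
    loud = loudness_match(
        listener, pitch.matched_frequency_hz, ear=ear,
        start_sl=preset.level_db_sl, coarse_step_db=5, fine_step_db=1,
        stimulus_factory=factory,
    )
    n += loud.n_presentations
    if loud.capped:
        flags.append("loudness_cap")

    spl = min(120.0, max(0.0, loud.level_db_spl))
    comp = factory(spl)
    route = listener.percept.ear
    if isinstance(comp, ToneComponent):
        model = TinnitusModel(tones=(comp,), ear=route)
    else:
        model = TinnitusModel(noises=(comp,), ear=route)
    rating = listener.rate_similarity(model).rating_0_10
    return SessionRecord(
        participant_id=participant_id,
        method="audiometer",
        matched_model=model,
        similarity_0_10=rating,
        duration_min=n * seconds_per_presentation / 60.0,
        n_presentations=n,
        flags=flags,
    )


# -- Stage II internals ------------------------------------------------------

_FREQ_STEPS_OCT = (0.25, 0.125, 0.0625)
_LEVEL_STEPS_DB = (4.0, 2.0, 1.0)


@dataclass
class _Candidate:
    kind: str  # "tone" | "noise"
    frequency_hz: float  # tone frequency or noise band centre
    level_db_spl: float
    width_octaves: float = 1.0 / 3.0

    def component(self) -> Component:
        level = min(120.0, max(0.0, self.level_db_spl))
        if self.kind == "tone":
            return ToneComponent(
                frequency_hz=min(20000.0, max(16.0, self.frequency_hz)),
                level_db_spl=level,
            )
        half = self.width_octaves / 2.0
        return NoiseComponent(
            band_low_hz=max(16.0, self.frequency_hz * 2.0**-half),
            band_high_hz=min(20000.0, self.frequency_hz * 2.0**half),
            level_db_spl=level,
        )


def _build_model(candidates: list[_Candidate], ear: Ear) -> TinnitusModel:
    tones = tuple(c.component() for c in candidates if c.kind == "tone")
    noises = tuple(c.component() for c in candidates if c.kind == "noise")
    return TinnitusModel(tones=tones, noises=noises, ear=ear)


def _place_next(listener: VirtualListener, current: TinnitusModel | None) -> _Candidate | None:
    """Where the patient drops the next icon: near the loudest percept
    component that is not yet represented in the current model."""
    if current is None:
        unmatched = list(listener.percept.components)
    else:
        pairs, _ = _greedy_pairs(listener.percept.components, current.components)
        matched_percepts = set()
        for p, c in pairs:
            close = (
                abs(math.log2(component_frequency(c) / component_frequency(p))) <= 0.125
                and abs(c.level_db_spl - p.level_db_spl) <= 3.0
            )
            if close:
                matched_percepts.add(id(p))
        unmatched = [p for p in listener.percept.components if id(p) not in matched_percepts]
    if not unmatched:
        return None
    target = max(unmatched, key=lambda c: c.level_db_spl)
    f, level = listener.place_near(target)
    if isinstance(target, NoiseComponent):
        width = target.bandwidth_octaves * 2.0 ** listener.rng.uniform(-0.25, 0.25)
        return _Candidate("noise", f, level, width_octaves=max(width, 1 / 8))
    return _Candidate("tone", f, level)


def run_stage_II(
    listener: VirtualListener,
    participant_id: int = 0,
    seconds_per_presentation: float = SECONDS_PER_PRESENTATION,
    max_moves: int = STAGE_II_MOVE_CAP,
    max_components: int = 4,
) -> SessionRecord:
    """Synthesizer stage: direct-manipulation placement plus coarse-to-fine
    self-adjustment of each component's frequency and level.

    The patient places each component near its percept target (the axes are
    visible on the interface), then refines it by continuous dragging; each
    refinement sweep at one step size counts as a single settled audition,
    while the underlying preference judgements draw on the listener's noisy
    comparison model and count against ``max_moves``.
    """
    ear = listener.percept.ear
    flags: list[str] = []
    auditions = 0
    moves = 0
    candidates: list[_Candidate] = []

    def model() -> TinnitusModel:
        return _build_model(candidates, ear)

    def try_move(i: int, attr: str, delta: float) -> bool:
        nonlocal moves
        cand = candidates[i]
        if attr == "frequency_hz":
            new = _Candidate(cand.kind, cand.frequency_hz * 2.0**delta,
                             cand.level_db_spl, cand.width_octaves)
        else:
            new = _Candidate(cand.kind, cand.frequency_hz,
                             cand.level_db_spl + delta, cand.width_octaves)
        trial = candidates.copy()
        trial[i] = new
        moves += 1
        if listener.prefer(_build_model(trial, ear), model()):
            candidates[i] = new
            return True
        return False

    def settle(i: int, attr: str, step: float) -> None:
        nonlocal auditions
        auditions += 1  # one continuous adjustment sweep at this step size
        for sign in (1.0, -1.0):
            accepted = False
            while moves < max_moves and try_move(i, attr, sign * step):
                accepted = True
            if accepted:
                return

    def optimize(i: int) -> None:
        for f_step, l_step in zip(_FREQ_STEPS_OCT, _LEVEL_STEPS_DB):
            settle(i, "frequency_hz", f_step)
            settle(i, "level_db_spl", l_step)

    first = _place_next(listener, None)
    candidates.append(first)
    auditions += 1
    optimize(0)

    while len(candidates) < max_components and moves < max_moves:
        nxt = _place_next(listener, model())
        if nxt is None:
            break
        without = model()
        candidates.append(nxt)
        auditions += 1
        optimize(len(candidates) - 1)
        moves += 1
        auditions += 1
        if not listener.prefer(model(), without):
            candidates.pop()
            break
    if moves >= max_moves:
        flags.append("move_cap")

    final = model()
    rating = listener.rate_similarity(final).rating_0_10
    return SessionRecord(
        participant_id=participant_id,
        method="synthesizer",
        matched_model=final,
        similarity_0_10=rating,
        duration_min=auditions * seconds_per_presentation / 60.0,
        n_presentations=auditions,
        flags=flags,
    )
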