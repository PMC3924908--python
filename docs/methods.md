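# Methods

## Signal model and calibration

All audio is rendered at 44.1 kHz into 3 s buffers (both configurable
through `RenderConfig`; the sample rate is fixed). Digital level follows a
single convention: a full-scale sinusoid (peak 1.0) represents
`calibration_offset_db` dB SPL, default 100. The level of any buffer is
`cal + 20·log10(RMS·√2)`, and every component is scaled to its target this
way, so levels are exact by construction rather than approximate. No
transducer-specific output calibration is attempted (rendering to physical
headphones would need per-device correction and is out of scope).

Tones are sampled sinusoids at any frequency from 1 Hz to 22 kHz (the
synthesis path additionally guards Nyquist). Noise components start from a
seeded Gaussian generator clipped at ±4σ — a reproducible stand-in for a
stored white-noise sample; a recorded WAVE can be substituted upstream —
and are shaped by the filterbank below. Amplitude modulation uses the
peak-preserving raised cosine

    m(t) = 1 − (depth/2)·(1 − cos 2π·rate·t),  0 < rate ≤ 20 Hz, 0 ≤ depth ≤ 1,

chosen so the envelope maximum stays at the calibrated level and the trough
is `1 − depth`. Its long-run RMS factor has the closed form
`√(1 − depth + 3·depth²/8)`, which the tests verify to 1%. The interface
labels map slow/fast → 0.5–8 Hz and weakly/strongly → depth 0.1–1.0.
Mixes that would clip are scaled down globally and the applied gain
reported, preserving spectral shape; the silent channel of a one-ear render
is exactly zero.

## The 1/8-octave filterbank

The multi-band equalizer uses 62 contiguous 1/8-octave bands. Sixty-two
such bands span 7.75 octaves, so they cannot cover the full 1 Hz–22 kHz
tone range; band centres are placed at `100·2^(k/8)` Hz (k = 0..61,
~100 Hz–19.7 kHz), covering the audiometric and tinnitus-relevant range
inside Nyquist while keeping the printed band count. Each band is a
windowed-sinc (Hamming) linear-phase band-pass whose −6 dB cutoffs sit
exactly on the band edges; tap counts scale inversely with the lower edge
(≈3.5·fs per 1/16-octave transition width, ~70k taps at 100 Hz down to a
few hundred at the top) so the transition band stays within 1/16 octave.
Filters are applied centred (`fftconvolve(..., "same")` on odd-length
kernels), i.e. zero phase, so multi-band sums stay delay-aligned:

* adjacent bands cross at amplitude 0.5 with identical phase, so any
  contiguous run of bands sums coherently to a flat response over its
  union — a noise band spanning several sub-bands has no crossover dips;
* the 62 magnitude responses sum to 1 within ±0.05 between the outermost
  band centres (tested with a ±0.15 budget);
* rejection one full band away from any edge exceeds 40 dB (measured
  ≈55 dB), i.e. >80 dB in power for filtered noise.

Noise synthesis draws `n + taps − 1` samples and keeps the valid part of
the convolution, so buffers are steady-state throughout and RMS calibration
is unbiased.

## Level scales

dB HL ↔ dB SPL conversions use an embedded RETSPL table for supra-aural
audiometric earphones (overridable by CSV, since transducers vary);
sensation level (dB SL) adds the individual's threshold on top. All
conversions are affine lookups, hence exactly invertible. Audiogram
thresholds off the audiometric grid are interpolated linearly in dB over
log2(frequency) — the interpolation runs on threshold *SPL* values so no
RETSPL value off the grid is ever needed. The audiometer model has the
fixed frequency set {125, 250, 500, 750, 1000, 1500, 2000, 3000, 4000,
6000, 8000} Hz, 5 dB steps (1 dB where the procedure calls for fine
matching), and 1/3-octave narrowband maskers with geometric edges
`center·2^(±1/6)` — the audiometric convention for "narrowband".

## The virtual listener

The simulated patient exists to make the procedures testable at desk scale;
its role is ordinal correctness, not human realism. It holds a ground-truth
percept (any tone/noise mixture with ear routing) and answers:

* **pitch**: sign of `log2(stimulus/percept) + N(0, pitch_jnd_octaves)`;
  exact ties read "stimulus higher" deterministically. 2AFC "which is
  closer" uses independent noise on both log-distances. A percept dominated
  by a noise band wider than 3 octaves has no dominant band and rejects
  pitch queries (narrower bands are pitch-matched through their centre, as
  clinical practice does).
* **loudness**: level difference plus `N(0, level_jnd_db)`, "equal" within
  half a JND but at least ±0.5 dB (half the finest 1 dB step, so noiseless
  staircases terminate). Stimuli below the audiogram threshold always read
  softer.
* **masking**: energetic rule — the percept is inaudible when the masker's
  effective level inside the percept's 1/3-octave neighbourhood (overall
  level minus a flat-spectrum bandwidth correction) reaches percept level
  minus a margin, default 10 dB, anchored to the observation that tinnitus
  typically masks within ~10 dB SL of its matched loudness.
* **similarity**: percept and candidate components are greedily paired by
  octave distance; the cost sums `d_f/1 oct + d_L/20 dB`, a unit penalty
  per tone/noise character mismatch and per unmatched component; the
  reported rating is `round(10·exp(−slope·cost))` clamped to 0–10, so an
  exact match rates 10 and every distance term lowers the rating
  monotonically. Pairwise preference uses the same cost with additive
  noise. The rating model is an invented instrument — no subject model
  exists to copy — and AM parameters do not enter it, so the session
  optimizer does not fit AM.

All randomness (JND noise, lapses with probability ≤0.2, residual
inhibition, interface placement) flows from one seeded generator; identical
seeds replay identical sessions. Rating drift over time ("patients change
their minds") is represented only by lapse noise, not modelled dynamically.

## Procedures

**Pitch matching** starts at 1000 Hz and walks the octave ladder in the
indicated direction until the judgement reverses, narrowing the percept to
one octave; the inter-octave audiometer frequency inside the bracket is
then pitted against both endpoints in 2AFC trials (two presentations each).
When endpoint wins conflict under response noise, a best-of-three forced
choice between the endpoints decides — the tie-break rule is ours, as no
standard exists. A noiseless listener always lands on the log-nearest set
frequency, so the audiometer's error is bounded by half the local gap of
its frequency set (at most half an octave).

**Loudness matching** starts at 15 dB SL (7.5 dB SL when the threshold
exceeds 20 dB HL, i.e. hypacusis), steps 5 dB until the first reversal and
1 dB thereafter until "equal". The examiner's initial coarse preset at
1000 Hz stops at the first reversal.

**Character check** presents the matched-pitch tone against the 1/3-octave
masker noise; ties keep the tone (the tone result is final unless noise is
actively preferred), and only a preferred noise triggers the broadband
comparison. The winner's loudness is re-matched at 1 dB.

**MML** tracks per-ear effective masking levels starting at each ear's
threshold, rising in joint 1 dB increments, continuing contralaterally once
one ear reports the tinnitus gone. Levels are book-kept as effective levels
at the percept's neighbourhood (so "MML = threshold + 10 dB for a percept
20 dB above threshold" holds in closed form under the masking rule); the
result also carries the equivalent overall broadband component. **Residual
inhibition** re-uses that masker at MML + 10 dB for a fixed 60 s and records
the listener's configured percentage reduction (a stub distribution, not a
neural model).

**Stage I** composes preset → pitch match → character check → final
loudness match; each audiometer stimulus counts as one presentation.
**Stage II** models the touch interface as 2-D direct manipulation: the
patient drops each component within ±1/2 octave and ±8 dB of its percept
target (the axes are visible and colour-coded), then refines frequency and
level by coordinate descent with step halving (1/4 → 1/8 → 1/16 octave;
4 → 2 → 1 dB), accepting moves the listener prefers. One continuous
adjustment sweep per step size counts as a single settled audition in the
duration proxy — dragging a slider while listening is one listening
episode, unlike discrete examiner-presented stimuli — while every
underlying preference query counts against the 500-move cap (Stage I caps
at 100 presentations; capped sessions are flagged, not dropped). Components
are added (up to 4) while the patient can still point to an unmatched
percept component, each addition confirmed by an explicit with/without
preference. Durations are presentation counts times a constant (default
10 s/presentation): human wall-clock time is not reproducible, and the
constant cancels in between-method comparisons.

Under these conditions a noiseless tonal listener recovers frequency within
1/16 octave and level within 1 dB in every seeded run, and the synthesizer
stage needs fewer presentations than the audiometer stage at the median
(typically ~7 vs ~16) — the direction the paired duration data show.

## Statistics

The Wilcoxon signed-rank implementation follows the exact convention of the
original analysis software: zero differences dropped, mid-ranks for ties,
T = smaller signed-rank sum, `Z = (μ_T − T)/σ_T` with **no continuity
correction and no tie-variance correction**, two-sided normal p, and effect
size `r = Z/√(n₁+n₂)` with the *total observation count* (both columns) in
the denominator. These choices are deliberate: with either correction, or
with the post-removal pair count in r, the bundled study table does not
reproduce its published Z, p and r values. An exact two-sided p by full
enumeration of sign assignments (n ≤ 20) serves as an independent oracle;
on the bundled samples the normal approximation sits within 0.004 of it.
scipy's signed-rank test cross-checks T in the test suite but is not the
implementation (its approximate p applies a tie correction).

Shapiro–Wilk uses the standard Royston approximation (via scipy) behind the
package's own surface. Box summaries use median-exclusive quartiles with
whiskers at the minimum and maximum (the study's own description of its box
plots, not 1.5·IQR fences).

## Fixtures and the synthetic-data generator

The bundled tables transcribe the study's per-participant results: 14
participants, per-ear matched components for both stages, similarity
ratings and durations. Demographics are stored verbatim even where the
source is internally inconsistent (e.g. its stated mean ages do not match
the printed rows), and reported noise-band centre frequencies (F_avg) are
kept as printed rather than recomputed from the rounded band edges, which
cannot reproduce them exactly.

`make_tonal_population` generates the simulation study's conditions:
single-tone percepts log-uniform in 250–8000 Hz at 5–25 dB SL over a flat
10 dB HL audiogram — matched tinnitus loudness clusters within a couple of
tens of dB SL of threshold, and the frequency range covers the audiometer's
inter-octave region. `make_study_population` mixes in narrow noise percepts
(4 in 14) to mirror the study group's composition. What these simulations
demonstrate is internal consistency — that the procedures recover what the
listener model encodes; they cannot validate the listener model against
human behaviour, response drift, or real masking physiology.

## Known limitations

* The filterbank covers ~100 Hz–20.6 kHz; tones below 100 Hz render
  directly but noise bands cannot be shaped there.
* The similarity model ignores AM and noise bandwidth, so Stage II does not
  fit AM parameters and band widths are only approximately placed.
* Loudness comparisons ignore frequency-dependent loudness (no phon
  weighting); levels compare in dB SPL.
* Residual inhibition is a configurable response distribution, not a model
  of suppression dynamics.
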