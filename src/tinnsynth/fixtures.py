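"""Bundled study fixtures: the published per-participant results tables.

``table1`` holds the per-component matching outcomes of both stages (one row
per matched component, long format); ``table2`` holds the paired
similarity-rating and test-duration columns used for the statistical
comparison.  Values are stored verbatim as printed — including the noise
bands' reported F_avg centre frequencies, which do not exactly equal the
mean of the rounded band edges and are therefore kept as data rather than
recomputed.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .models import Ear, NoiseComponent, TinnitusModel, ToneComponent

TABLE2_PAIRS = {
    "similarity": ("similarity_audiometer", "similarity_synthesizer"),
    "duration": ("duration_audiometer", "duration_synthesizer"),
}


def _data_path(name: str):
    return resources.files("tinnsynth").joinpath("data", name)


def load_table2(path: str | Path | None = None) -> pd.DataFrame:
    """Paired similarity and duration columns, one row per participant."""
    src = Path(path) if path is not None else _data_path("table2.csv")
    df = pd.read_csv(src)
    required = {"participant", *[c for pair in TABLE2_PAIRS.values() for c in pair]}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"table2 fixture missing columns: {sorted(missing)}")
    return df


def load_table1(path: str | Path | None = None) -> pd.DataFrame:
    """Per-component matching results of both stages (long format)."""
    src = Path(path) if path is not None else _data_path("table1.csv")
    return pd.read_csv(src)


def participant_model(
    table1: pd.DataFrame, participant: int, stage: str
) -> TinnitusModel:
    """Build the matched :class:`TinnitusModel` of one participant/stage.

    Components routed to a single ear produce an ``ear``-routed model; when
    both ears received (possibly different) components the model is routed
    to both ears with all components pooled.
    """
    rows = table1[(table1.participant == participant) & (table1.stage == stage)]
    if rows.empty:
        raise ValueError(f"no rows for participant {participant} stage {stage}")
    tones, noises = [], []
    for _, row in rows.iterrows():
        if row.stimulus_class == "noise":
            noises.append(
                NoiseComponent(
                    band_low_hz=row.band_low_hz,
                    band_high_hz=row.band_high_hz,
                    level_db_spl=row.level_db_spl,
                )
            )
        elif row.stimulus_class == "narrowband":
            center = float(row.frequency_hz)
            noises.append(
                NoiseComponent(
                    band_low_hz=center * 2 ** (-1 / 6),
                    band_high_hz=center * 2 ** (1 / 6),
                    level_db_spl=row.level_db_spl,
                )
            )
        else:
            tones.append(
                ToneComponent(
                    frequency_hz=row.frequency_hz, level_db_spl=row.level_db_spl
                )
            )
    ears = set(rows.ear)
    ear = Ear(next(iter(ears))) if len(ears) == 1 else Ear.both
    return TinnitusModel(tones=tuple(tones), noises=tuple(noises), ear=ear)
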