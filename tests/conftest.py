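import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from tinnsynth.calibration import Audiogram
from tinnsynth.filterbank import default_filterbank
from tinnsynth.fixtures import load_table2
from tinnsynth.listener import VirtualListener
from tinnsynth.models import Ear, RenderConfig, TinnitusModel, ToneComponent


@pytest.fixture(scope="session")
def config():
    return RenderConfig()


@pytest.fixture(scope="session")
def bank():
    return default_filterbank()


@pytest.fixture(scope="session")
def table2():
    return load_table2()


def tonal_listener(frequency_hz=4000.0, level_db_spl=60.0, **kwargs):
    """A single-tone virtual listener over a flat 10 dB HL audiogram."""
    percept = TinnitusModel(
        tones=(ToneComponent(frequency_hz=frequency_hz, level_db_spl=level_db_spl),),
        ear=Ear.both,
    )
    return VirtualListener(percept=percept, audiogram=Audiogram.flat(10.0), **kwargs)
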