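import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("suite")

from seedseq.fixtures import (
    FixtureSpec,
    generate_conservation,
    generate_library,
    generate_transcriptome,
)


@pytest.fixture(scope="session")
def spec():
    return FixtureSpec(rng_seed=42)


@pytest.fixture(scope="session")
def library(spec):
    return generate_library(spec)


@pytest.fixture(scope="session")
def transcriptome(spec, library):
    return generate_transcriptome(spec, library)


@pytest.fixture(scope="session")
def conservation(spec, transcriptome):
    transcripts, manifest = transcriptome
    return generate_conservation(spec, transcripts, manifest)


@pytest.fixture(scope="session")
def printed_record_path():
    from importlib.resources import files

    return str(files("seedseq").joinpath("data/GXP_170357.seedseq"))
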