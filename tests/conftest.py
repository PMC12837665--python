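import io

import pytest
from hypothesis import HealthCheck, settings

from mitocodon.genetic_code import load_code
from mitocodon.pipeline import AnalysisConfig
from mitocodon.synthetic_mito import SyntheticSpec, generate_genome_record, write_genbank

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def code2():
    return load_code(2)


@pytest.fixture(scope="session")
def code1():
    return load_code(1)


@pytest.fixture(scope="session")
def default_spec():
    return SyntheticSpec(seed=11)


@pytest.fixture(scope="session")
def synthetic_record(default_spec):
    return generate_genome_record(default_spec)


@pytest.fixture(scope="session")
def genbank_text(synthetic_record):
    buf = io.StringIO()
    write_genbank(synthetic_record, buf)
    return buf.getvalue()


@pytest.fixture(scope="session")
def config():
    return AnalysisConfig()
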