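import pytest
from hypothesis import settings

import mitocomp as mc

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def code():
    return mc.INVERTEBRATE_MITO


@pytest.fixture(scope="session")
def bx_table():
    return mc.load_template_table("bxylophilus")


@pytest.fixture(scope="session")
def pv_table():
    return mc.load_template_table("pvulnus")


@pytest.fixture(scope="session")
def bx_synth():
    """Synthetic genome realizing the B. xylophilus layout template."""
    spec = mc.GenomeSpec.from_template("bxylophilus", seed=2024)
    return mc.generate_genome(spec)


@pytest.fixture(scope="session")
def pv_synth():
    """Synthetic genome realizing the P. vulnus layout template."""
    spec = mc.GenomeSpec.from_template("pvulnus", seed=2025)
    return mc.generate_genome(spec)
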