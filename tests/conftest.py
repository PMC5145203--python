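import pytest

from gh2arch.synth import SynthConfig, generate


@pytest.fixture(scope="session")
def clean_dataset():
    """Default zero-noise scenario (60 taxa, rate 0.1)."""
    return generate(SynthConfig(seed=11))


@pytest.fixture(scope="session")
def small_dataset():
    """A small scenario for tree-stage tests."""
    return generate(SynthConfig(seed=5, n_taxa=20))
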