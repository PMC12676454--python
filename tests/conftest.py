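import pytest

from mpdiag import GeneratorConfig, build_mpd, egfr_model, random_model

CORPUS_SEEDS = range(100)


@pytest.fixture(scope="session")
def egfr():
    return egfr_model()


@pytest.fixture(scope="session")
def egfr_graph1(egfr):
    return build_mpd(egfr, 1)


@pytest.fixture(scope="session")
def egfr_graph3(egfr):
    return build_mpd(egfr, 3)


@pytest.fixture(scope="session")
def corpus():
    """100 seeded random models used by the property suites."""
    return [random_model(GeneratorConfig(seed=s)) for s in CORPUS_SEEDS]
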