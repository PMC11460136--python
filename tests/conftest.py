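import pytest

from herbq import discover_panel, fritillaria_demo


@pytest.fixture(scope="session")
def demo():
    """Eleven-species synthetic Fritillaria dataset: (grouping, alignments)."""
    return fritillaria_demo(seed=0)


@pytest.fixture(scope="session")
def grouping(demo):
    return demo[0]


@pytest.fixture(scope="session")
def alignments(demo):
    return demo[1]


@pytest.fixture(scope="session")
def panel(demo):
    g, alns = demo
    return discover_panel(alns, g)
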