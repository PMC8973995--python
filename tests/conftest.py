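import pytest

from trfnet import simulate as sim


@pytest.fixture(scope="session")
def small_config() -> sim.SimulationConfig:
    """A desk-scale configuration shared by unit tests."""
    return sim.SimulationConfig(
        seed=7, n_trnas=6, n_mrna=200, n_mirna=40, n_trf=30,
        planted_up={"mRNA": 20, "miRNA": 4, "tRF": 2},
        planted_down={"mRNA": 10, "miRNA": 3, "tRF": 4},
        reads_per_class=10,
    )


@pytest.fixture(scope="session")
def refs(small_config):
    return sim.make_trna_reference(small_config)
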