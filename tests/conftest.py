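import numpy as np
import pytest

from cfprs import panel as panel_mod


@pytest.fixture(scope="session")
def tiny_config() -> panel_mod.SimConfig:
    """A desk-scale simulator config small enough for per-test imputation."""
    return panel_mod.SimConfig(
        n_panel_haplotypes=60,
        n_sites=400,
        n_founders=10,
        region_length_bp=4_000_000,
        seed=101,
    )


@pytest.fixture(scope="session")
def tiny_panel(tiny_config) -> panel_mod.HaplotypePanel:
    return panel_mod.generate_panel(tiny_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260924)
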