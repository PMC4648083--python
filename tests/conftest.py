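import numpy as np
import pytest

from peagp import simdata


@pytest.fixture(scope="session")
def small_map():
    return simdata.simulate_map(simdata.SimMapConfig(n_markers=300, seed=11))


@pytest.fixture(scope="session")
def panel(small_map):
    gm, labels = simdata.simulate_panel(
        small_map, simdata.PanelSimConfig(n_accessions=150, seed=12)
    )
    return gm, labels


@pytest.fixture(scope="session")
def trait(panel):
    gm, _ = panel
    pheno, truth = simdata.simulate_trait(
        gm,
        simdata.TraitSimConfig(
            n_qtl=60, h2=0.9, seed=13, trait_name="t", gxy_sd_fraction=0.2, block_sd=1.0
        ),
    )
    return pheno, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
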