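import numpy as np
import pytest

from excessh2.heritability import Model, ModelSpec, build_tagging_table
from excessh2.panel import filter_variants, ld_r2
from excessh2.synthetic import PhenotypeSpec, SimulationConfig, gen_panel, gen_phenotype_catalog


@pytest.fixture(scope="session")
def default_panel():
    """Medium synthetic panel shared across tests (404 x 1500, blocks of 10)."""
    cfg = SimulationConfig(
        n_individuals=404,
        n_variants=1500,
        block_size=10,
        within_block_r2=0.6,
        seed=11,
    )
    return filter_variants(gen_panel(cfg))


@pytest.fixture(scope="session")
def default_ld(default_panel):
    return ld_r2(default_panel, window_kb=1000.0)


@pytest.fixture(scope="session")
def thin_tagging(default_panel, default_ld):
    spec = ModelSpec(model=Model.LDAK_THIN, alpha=-0.25)
    return build_tagging_table(default_panel.variants, default_ld, spec)


@pytest.fixture(scope="session")
def ldak_tagging(default_panel, default_ld):
    spec = ModelSpec(model=Model.LDAK, alpha=-0.25)
    return build_tagging_table(default_panel.variants, default_ld, spec)


@pytest.fixture(scope="session")
def default_catalog(default_panel):
    specs = [
        PhenotypeSpec("alcohol", 98, 1),
        PhenotypeSpec("insomnia", 244, 1),
        PhenotypeSpec("napping", 36, 0),
    ]
    return gen_phenotype_catalog(default_panel, core_size=363, specs=specs, seed=7)
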