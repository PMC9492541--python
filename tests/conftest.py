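import pytest

from opisthotraj import parse_species_tree, simulate_gene_content
from opisthotraj.simulate import SimConfig, build_fixture


@pytest.fixture(scope="session")
def planted_sim():
    """One simulated dataset with a clade-A gain bias toward K, T and W."""
    cfg = SimConfig(seed=11, clade_multipliers={"A": {"K": 2.0, "T": 2.0, "W": 2.0}})
    events, truth = simulate_gene_content(cfg)
    return cfg, events, truth


@pytest.fixture(scope="session")
def neutral_sim():
    """A simulated dataset with no clade bias (null conditions)."""
    cfg = SimConfig(seed=23)
    events, truth = simulate_gene_content(cfg)
    return cfg, events, truth


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    cfg = SimConfig(seed=7, p_multi=0.05, p_unannotated=0.1,
                    clade_multipliers={"A": {"K": 2.0, "T": 2.0, "W": 2.0}})
    out = tmp_path_factory.mktemp("fixture")
    return build_fixture(cfg, out), cfg


@pytest.fixture
def four_tip_tree():
    return parse_species_tree("((a,b)M,(c,d)F)O;")
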