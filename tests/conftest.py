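import pytest

from clonevar import simdata
from clonevar.junction import locus_model_from_scenario


@pytest.fixture(scope="session")
def genome():
    return simdata.make_reference(10_000, 2, seed=7)


@pytest.fixture(scope="session")
def simplex_scenario():
    """Non-chimeric tetraploid with one constitutive scar haplotype."""
    return simdata.default_scenario(seed=11, genotype="simplex_scar")


@pytest.fixture(scope="session")
def simplex_sim(simplex_scenario):
    sc = simplex_scenario
    return simdata.simulate_chimera_reads(
        sc.genome, sc.haplotypes, sc.chimera, sc.params)


@pytest.fixture(scope="session")
def simplex_model(simplex_scenario):
    return locus_model_from_scenario(simplex_scenario)


@pytest.fixture(scope="session")
def rn_scenario():
    """Progenitor genotype: two intact and two TE haplotypes, no chimera."""
    return simdata.default_scenario(seed=13, genotype="rn")
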