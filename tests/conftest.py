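import numpy as np
import pytest

from admixomics import ancestry, synth


@pytest.fixture(scope="session")
def small_panel():
    """3 well-separated populations, 60/pop, 1,500 SNPs (session-cached)."""
    model = synth.PopulationModel(n_pops=3, n_snps=1500, fst=0.1)
    return synth.simulate_reference_panel(model, 60, seed=11)


@pytest.fixture(scope="session")
def small_pca(small_panel):
    return ancestry.fit_reference_pca(small_panel.panel, n_axes=4)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
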