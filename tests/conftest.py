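import numpy as np
import pytest

import nupfret as nf


@pytest.fixture()
def clean_mixture_bursts():
    """5000-burst 50/50 mixture of E = 0.6 / 0.2 without contaminants."""
    species = [nf.FretSpecies(0.6, 0.5), nf.FretSpecies(0.2, 0.5)]
    config = nf.BurstGenConfig(n_bursts=5000, seed=42)
    return nf.simulate_bursts(species, config)


@pytest.fixture()
def contaminated_mixture_bursts():
    """Mixture including donor-only / acceptor-only contaminant species."""
    species = nf.two_state_species(fraction_bound=0.5, donor_only=0.2, acceptor_only=0.05)
    return nf.simulate_bursts(species, nf.BurstGenConfig(n_bursts=5000, seed=7))


@pytest.fixture(scope="session")
def gaussian_chain():
    """101-residue ideal chain, 4000 conformers, bond 0.38 nm."""
    return nf.simulate_gaussian_chain(101, bond_length=0.38, n_models=4000, seed=11)
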