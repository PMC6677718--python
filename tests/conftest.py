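import numpy as np
import pytest

from hybridrd import (Domain, EMConfig, Partition, ReactionSpec, SchemeConfig,
                      SpeciesSpec, build_model, morphogen_model,
                      two_compartment_model)

DT = 5e-4


@pytest.fixture(scope="session")
def morphogen():
    """Morphogen model with its default half-domain partition (alpha=5)."""
    return morphogen_model(alpha=5)


@pytest.fixture(scope="session")
def two_comp():
    """Two-compartment pure-diffusion model (alpha=10)."""
    return two_compartment_model(alpha=10)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def pure_death_model():
    """Single compartment, pure degradation at 0.05/s from 500 molecules."""
    dom = Domain.from_compartments(K=1, h=1.0)
    deg = ReactionSpec.first("degradation", "S", {"S": -1}, 0.05)
    return build_model(dom, [SpeciesSpec("S", 0.0)], [deg], np.array([[500]]))
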