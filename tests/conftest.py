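import numpy as np
import pytest

from cglipid.synthetic import (
    FixtureSpec,
    default_toy_forcefield,
    expand_pseudo_atomistic,
    generate_cg_dataset,
)


@pytest.fixture(scope="session")
def toy_ff():
    return default_toy_forcefield()


@pytest.fixture(scope="session")
def bilayer_spec():
    # small but genuinely bilayer-shaped: 16 lipids, 96 beads
    return FixtureSpec(
        n_lipids=16,
        geometry="bilayer",
        n_frames=25,
        seed=3,
        burn_in_steps=600,
        sample_interval=60,
        timestep=10.0,
    )


@pytest.fixture(scope="session")
def bilayer_data(bilayer_spec, toy_ff):
    return generate_cg_dataset(bilayer_spec, toy_ff)


@pytest.fixture(scope="session")
def expanded(bilayer_data, bilayer_spec):
    frames, scheme = expand_pseudo_atomistic(
        bilayer_data, bilayer_spec.atoms_per_bead, seed=bilayer_spec.seed + 1
    )
    return frames, scheme


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
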