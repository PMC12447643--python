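import pytest

from cd300evo.simulate import SimConfig, make_reference_fixture, simulate_family


@pytest.fixture(scope="session")
def ref_pair():
    """Synthetic A-like / C-like reference annotations."""
    return make_reference_fixture()


@pytest.fixture(scope="session")
def quiet_sim():
    """Substitution-only simulation: no conversion, no inactivation."""
    return simulate_family(
        SimConfig(seed=11, conversion_rate=0.0, pseudogen_prob=0.0, loss_prob=0.0)
    )


@pytest.fixture(scope="session")
def lesioned_sim():
    """Simulation with frequent pseudogenization and loss on gene C."""
    return simulate_family(
        SimConfig(seed=23, conversion_rate=0.0, pseudogen_prob=0.3, loss_prob=0.15)
    )
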