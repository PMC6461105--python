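import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from auroraloop.simulate import EmissionModel, SimulationConfig, TwoStateRates, simulate_ensemble

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

# kinetic regimes matching the two measured phosphorylation states
RATES_UNPHOS = TwoStateRates(k_active=2.1, k_inactive=2.4)   # ~53.3% inactive
RATES_PHOS = TwoStateRates(k_active=2.3, k_inactive=0.7)     # ~23.3% inactive


@pytest.fixture(scope="session")
def ensemble_unphos():
    cfg = SimulationConfig(rates=RATES_UNPHOS, n_molecules=250, seed=11)
    return simulate_ensemble(cfg)


@pytest.fixture(scope="session")
def ensemble_phos():
    cfg = SimulationConfig(rates=RATES_PHOS, n_molecules=250, seed=12)
    return simulate_ensemble(cfg)


@pytest.fixture(scope="session")
def well_separated_ensemble():
    """High-contrast emission (modes 1 and 10) for mode-recovery checks."""
    cfg = SimulationConfig(
        rates=RATES_UNPHOS,
        emission=EmissionModel(mode_high=10.0, mode_low=1.0, shape_high=0.15, shape_low=0.15),
        n_molecules=150,
        seed=13,
    )
    return simulate_ensemble(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(2026)
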