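import numpy as np
import pytest

from pcdenoise import PhaseCouplingDecomposition, TrialConfig, simulate_trial


@pytest.fixture(scope="session")
def realistic_trial():
    """One contaminated realistic trial (16 ch, 3 bursts + MCAS artifact)."""
    return simulate_trial(TrialConfig(scenario="realistic", seed=0, agr_db=0.0))


@pytest.fixture(scope="session")
def fitted_results(realistic_trial):
    trial, _ = realistic_trial
    return PhaseCouplingDecomposition.from_trial(trial).fit()


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
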