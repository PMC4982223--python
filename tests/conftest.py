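import numpy as np
import pytest

from gliodiff.model import Ensemble, default_initial_state, default_parameters


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def basal():
    """Frozen untreated steady state (verified against long integration)."""
    return default_initial_state()


def make_gfap_ensemble(values, t=(0.0, 48.0)):
    """Ensemble whose GFAP level is constant at the given per-cell values."""
    values = np.asarray(values, dtype=float)
    states = np.zeros((values.size, len(t), 10))
    states[:, :, 9] = values[:, None]
    return Ensemble(
        t=np.asarray(t), states=states, CT=10.0, regime="anm",
        master_seed=0, trajectory_seeds=list(range(values.size)),
    )
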