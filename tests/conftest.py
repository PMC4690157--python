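import numpy as np
import pytest

from sulfrac import DeltaTriple
from sulfrac.synthetic_data import DEFAULT_SCHEME, DEFAULT_TRUTH, ExperimentDesign


@pytest.fixture(scope="session")
def truth_branch():
    """Reference truth: reduced-branch eps 15.3 permil / lambda 0.5150,
    sulfonate-branch eps -3.2 permil / lambda 0.495 (r-p convention)."""
    return DEFAULT_TRUTH


@pytest.fixture(scope="session")
def scheme():
    return DEFAULT_SCHEME


@pytest.fixture(scope="session")
def delta0():
    return DeltaTriple(d34=0.0, d33=0.0, d36=0.0)


@pytest.fixture(scope="session")
def early_grid():
    """8 points spanning the early-reaction window 0.99 -> 0.85."""
    return np.linspace(0.99, 0.85, 8)


@pytest.fixture(scope="session")
def early_design(early_grid):
    return ExperimentDesign(f_grid=tuple(early_grid))


@pytest.fixture()
def noise_free_frame(truth_branch, scheme, delta0, early_grid):
    from sulfrac.forward_model import simulate

    traj = simulate(truth_branch, scheme, 15.0, delta0, early_grid)
    return traj.to_frame()
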