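import pytest

from p53lcm import published
from p53lcm.fixtures import load_study_panel
from p53lcm.lcm import EmSettings, LcmSpec


@pytest.fixture(scope="session")
def study_panel():
    """The frozen 911-subject panel consistent with the published
    pairwise cross-tabulations."""
    return load_study_panel()


@pytest.fixture(scope="session")
def spec3():
    return LcmSpec(3, published.TEST_NAMES)


@pytest.fixture(scope="session")
def fast_spec3():
    """Few restarts: used where the optimum is well separated and many
    fits are run."""
    return LcmSpec(3, published.TEST_NAMES, em=EmSettings(n_restarts=2, seed=0))


@pytest.fixture(scope="session")
def interior_thetas():
    """Published classification matrices smoothed away from the boundary
    (2% uniform mass) so that chi-square asymptotics apply."""
    th = published.classification_matrices()
    return 0.98 * th + 0.02 / 3.0
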