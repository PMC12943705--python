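import numpy as np
import pytest

import greenflow as gf
from greenflow import doe


@pytest.fixture(scope="session")
def factors():
    return gf.default_factors()


@pytest.fixture(scope="session")
def design():
    """Default 15-run screening design."""
    return gf.generate_dsd(seed=1)


@pytest.fixture(scope="session")
def campaign(design):
    """One simulated campaign on the default design."""
    return gf.simulate_campaign(design, seed=7)


@pytest.fixture(scope="session")
def campaign_xy(design, campaign):
    coded = np.vstack([doe.encode_levels(r.conditions, design.factors) for r in campaign])
    y = np.array([r.lanosterol_yield for r in campaign])
    return coded, y


@pytest.fixture(scope="session")
def fitted_model(campaign_xy):
    coded, y = campaign_xy
    return gf.backward_eliminate(coded, y, alpha=0.10)
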