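import numpy as np
import pytest

import tradeflow as tf
from tradeflow.netmodel import FitConfig


@pytest.fixture(scope="session")
def small_config():
    return tf.SyntheticConfig(
        n_countries=6,
        n_years=3,
        seed=42,
        beta=np.r_[4.0, 1.0, -0.3, np.zeros(8)],
        phi_matrix=[[0.6, 0.0], [0.0, 0.4]],
        phi_gg=0.3,
        rho=0.5,
        sigma2_gamma=0.5,
        sigma_eps=np.eye(2) * 0.2,
        agreement_prob=0.4,
    )


@pytest.fixture(scope="session")
def small_data(small_config):
    panel, dyads = tf.generate_country_panel(small_config)
    tensor, truth = tf.simulate_trade_tensor(panel, dyads, small_config)
    return panel, dyads, tensor, truth


@pytest.fixture(scope="session")
def small_design(small_data):
    panel, dyads, tensor, _ = small_data
    return tf.build_design_matrices(panel, dyads, tensor)


@pytest.fixture(scope="session")
def small_draws(small_design):
    return tf.gibbs_fit(
        small_design, FitConfig(iterations=300, burn_in=100, thin=2, seed=1)
    )
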