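import numpy as np
import pytest

from cuebias.data import filter_rts
from cuebias.hierarchical import build_model, sample_posterior
from cuebias.synthetic import GroupTruth, SyntheticConfig, generate_study


@pytest.fixture(scope="session")
def small_study():
    """A 12-participant M1-generated study (positive starting-point effect)."""
    cfg = SyntheticConfig(
        n_participants=12,
        n_blocks=3,
        trials_per_block=40,
        truth=GroupTruth(theta_start=1.2, sigma_start=0.05),
        trait_correlation=0.0,
        seed=1234,
    )
    data, participants = generate_study(cfg)
    filtered, _ = filter_rts(data)
    return cfg, filtered, participants


@pytest.fixture(scope="session")
def fitted_m1(small_study):
    """A short M1 fit on the small study, shared across tests."""
    _, data, _ = small_study
    model = build_model("M1_start", data)
    draws = sample_posterior(model, n_chains=2, n_iter=900, burn_in=400, seed=321)
    return model, draws
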