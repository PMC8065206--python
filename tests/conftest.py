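import pytest

from ntekinetics.models import build_model
from ntekinetics.synthetic import SyntheticConfig, default_design, generate_processed

#: Fitted parameters of the best-supported variant on the source study's
#: full dataset; used throughout as generative truth.
TRUTH = {"B": 0.424, "kNTE": 0.166, "kTE_LMH": 0.027, "kTE_VH": 0.127}


@pytest.fixture(scope="session")
def best_spec():
    return build_model("NTE_TE_lin_S2")


@pytest.fixture(scope="session")
def study_scale_data():
    """One ~920-sample dataset at the emulated study's design and noise."""
    return generate_processed(SyntheticConfig(seed=42))


@pytest.fixture(scope="session")
def small_design():
    """~90-sample design for fast fitting tests."""
    return default_design(n_rats_per_cell=2, n_sham_rats=6)


@pytest.fixture()
def small_data(small_design):
    return generate_processed(SyntheticConfig(seed=7, design=small_design))


@pytest.fixture(scope="session")
def noiseless_data():
    return generate_processed(
        SyntheticConfig(seed=3, noise_sd=1e-12, rat_sd=0.0)
    )
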