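import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from methylsplit.pipeline import RunConfig, run_detect
from methylsplit.simulate import simulate_dataset

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

# A seed fixed for the whole suite; small pipeline fixtures derive from it.
SUITE_SEED = 20170512


@pytest.fixture(scope="session")
def small_dataset():
    """120-kb simulated dataset with six insertions (two per context)."""
    return simulate_dataset(
        SUITE_SEED,
        genome_length=120_000,
        coverage=20,
        read_len=100,
        n_per_context={"genic": 2, "intergenic": 2, "TE": 2},
    )


@pytest.fixture(scope="session")
def small_run(small_dataset):
    ds = small_dataset
    result = run_detect(ds.reference, ds.te_annot, ds.reads, RunConfig())
    return ds, result


@pytest.fixture()
def rng():
    return np.random.default_rng(SUITE_SEED)
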