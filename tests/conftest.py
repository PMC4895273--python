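import numpy as np
import pytest

from rsaboost.fixtures import FixtureSpec, generate, generate_records, worked_example


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def small_records():
    """Ten short planted-signal proteins shared across pipeline tests."""
    return generate_records(FixtureSpec(n_proteins=10, length_range=(40, 60), seed=11))


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """An on-disk fixture manifest matching ``small_records``."""
    outdir = tmp_path_factory.mktemp("fixtures")
    manifest = generate(
        FixtureSpec(n_proteins=10, length_range=(40, 60), seed=11), outdir
    )
    return manifest


@pytest.fixture(scope="session")
def worked():
    record, classes = worked_example()
    return record, classes
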