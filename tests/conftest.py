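import numpy as np
import pytest

from ippispace import DatasetSpec, default_specs, generate_collection


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20160401)


@pytest.fixture(scope="session")
def default_collection():
    """The joined synthetic iPPI-DB-like + TIMBAL-like table (3,248 rows)."""
    return generate_collection(default_specs())


@pytest.fixture()
def small_spec():
    return DatasetSpec(
        name="toy",
        n=200,
        means={"a": 0.0, "b": 10.0},
        sds={"a": 1.0, "b": 2.0},
        seed=7,
    )
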