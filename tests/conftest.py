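import numpy as np
import pytest

from phenocloud.synthfield import FieldSpec, generate_field


@pytest.fixture(scope="session")
def default_field():
    """One seeded 3x3 field at study-condition defaults, shared read-only."""
    return generate_field(FieldSpec(seed=1))


@pytest.fixture(scope="session")
def single_plant_field():
    """One isolated plant with its ground patch."""
    return generate_field(FieldSpec(rows=1, cols=1, seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
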