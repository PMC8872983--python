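import numpy as np
import pytest

from psychgen._types import ItemSpec
from psychgen.simulate import AceSpec, gen_item_responses


@pytest.fixture(scope="session")
def small_bank():
    """Three well-separated 2PL items."""
    return [
        ItemSpec("i1", "verbal", "vocabulary", a=1.0, b=-1.0),
        ItemSpec("i2", "verbal", "vocabulary", a=1.5, b=0.0),
        ItemSpec("i3", "nonverbal", "matrix_reasoning", a=2.0, b=1.0),
    ]


@pytest.fixture(scope="session")
def five_item_params():
    """Calibration-style parameter table for oracle checks."""
    import pandas as pd

    return pd.DataFrame(
        {"a": [0.8, 1.2, 1.6, 1.0, 2.0], "b": [-1.5, -0.5, 0.0, 0.8, 1.5],
         "c": [0.0] * 5},
        index=pd.Index([f"i{j}" for j in range(5)], name="item_id"),
    )


@pytest.fixture(scope="session")
def g_ace_spec():
    """ACE spec matching rMZ = 0.650, rDZ = 0.365."""
    return AceSpec(a2=0.57, c2=0.08, e2=0.35)


@pytest.fixture(scope="session")
def medium_responses(small_bank):
    return gen_item_responses(small_bank, 5000, seed=123)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
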