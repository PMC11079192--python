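import numpy as np
import pytest

from cerebsim.network import Hemisphere, build_cerebellum
from cerebsim.rng import SeedTable

MINI_COUNTS = {"MF": 2, "CF": 1, "GrC": 8, "GoC": 2, "MLI": 1, "PkC": 1}
MINI_CONVERGENCE = {
    ("GrC", "MF"): 2,
    ("GrC", "GoC"): 1,
    ("GoC", "MF"): 2,
    ("GoC", "GrC"): 3,
    ("PkC", "GrC"): "all",
    ("PkC", "MLI"): 1,
    ("MLI", "GrC"): 2,
}


def make_mini_hemisphere(seed=11, **kw) -> Hemisphere:
    """A miniature single hemisphere for oracle and equivalence tests."""
    return Hemisphere(
        "L", SeedTable(seed), counts=MINI_COUNTS, convergence=MINI_CONVERGENCE, **kw
    )


@pytest.fixture
def mini_hemisphere():
    return make_mini_hemisphere()


@pytest.fixture(scope="session")
def default_topology():
    return build_cerebellum(1)
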