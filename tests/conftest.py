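import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import taxsim as ts

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy5():
    return ts.toy5()


@pytest.fixture(scope="session")
def icd():
    """Derived ICD-10-style hierarchy covering all five levels."""
    return ts.derive_icd10_hierarchy(["M06.9", "M12.0", "I00.x01", "N18.5", "E11"])


@pytest.fixture(scope="session")
def small_tax():
    """Regular generated taxonomy with 6 chapters, 288 leaves."""
    return ts.gen_taxonomy(ts.TaxonomyGenSpec(levels=5, branching=(6, 4, 4, 3)))


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture(scope="session")
def toy5_file(tmp_path_factory):
    path = tmp_path_factory.mktemp("tax") / "toy5.tsv"
    ts.save_edge_list(ts.toy5(), path)
    return path
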