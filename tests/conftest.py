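import pytest

from feedval.io import load_compositions, load_fixture
from feedval.pipeline import build_ingredient_table, default_bundle
from feedval.synthetic import (
    BASAL_DIET_ID,
    default_energy_truth,
    default_ileal_truth,
    generate_design,
)

ESBM_IDS = [f"ESBM {i}" for i in range(1, 11)]


@pytest.fixture(scope="session")
def bundle():
    return default_bundle()


@pytest.fixture(scope="session")
def ingredient_table(bundle):
    """DM-basis ingredient table: composition + energies + SIDs, n = 10."""
    return build_ingredient_table(bundle)


@pytest.fixture(scope="session")
def table6_compositions():
    return load_compositions("table6")


@pytest.fixture(scope="session")
def table9():
    return load_fixture("table9")


@pytest.fixture(scope="session")
def table12():
    return load_fixture("table12")


@pytest.fixture(scope="session")
def energy_truth():
    return default_energy_truth()


@pytest.fixture(scope="session")
def ileal_truth():
    return default_ileal_truth()


@pytest.fixture(scope="session")
def energy_plan():
    """Replicated 11-diet x 3-period square: 22 pigs, 6 replicates/diet."""
    return generate_design(
        22, 11, 3, 6, seed=7, diet_ids=[BASAL_DIET_ID, *ESBM_IDS]
    )


@pytest.fixture(scope="session")
def ileal_plan():
    """10-diet x 6-period square: 10 pigs, 6 replicates/diet."""
    return generate_design(10, 10, 6, 6, seed=11, diet_ids=ESBM_IDS)
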