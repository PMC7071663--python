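import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import prioritycompass as pc

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def who_catalog() -> pc.InterventionCatalog:
    return pc.who_reference_catalog()


@pytest.fixture(scope="session")
def iran_mentions() -> pd.DataFrame:
    return pc.iran_mention_fixture()


@pytest.fixture(scope="session")
def iran_labels(who_catalog, iran_mentions) -> dict:
    return pc.label_interventions(who_catalog, iran_mentions)


@pytest.fixture(scope="session")
def claims_records() -> pd.DataFrame:
    return pc.reference_claims()


@pytest.fixture(scope="session")
def printed_weights() -> np.ndarray:
    return np.asarray(pc.REFERENCE_WEIGHTS, dtype=float)
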