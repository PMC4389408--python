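import numpy as np
import pandas as pd
import pytest

from tnbcsub.simulate import (
    CohortSpec,
    MacrophageSpec,
    generate_macrophage_reference,
    generate_tnbc_cohort,
)


@pytest.fixture(scope="session")
def cohort():
    """Default synthetic discovery cohort, shared across the suite."""
    return generate_tnbc_cohort(CohortSpec(seed=11))


@pytest.fixture(scope="session")
def macrophage_ref():
    return generate_macrophage_reference(MacrophageSpec(seed=11))


@pytest.fixture(scope="session")
def linked_cohort(macrophage_ref):
    """Cohort carrying the macrophage reference genes with planted directions."""
    return generate_tnbc_cohort(CohortSpec(seed=11), macrophage_truth=macrophage_ref.truth)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def toy_expression():
    """Small probe-level matrix with a multi-probe gene."""
    return pd.DataFrame(
        {
            "s1": [4.0, 6.0, 3.0, 9.0, 10.0],
            "s2": [5.0, 5.0, 2.0, 8.0, 11.0],
        },
        index=pd.Index(["gA_p1", "gA_p2", "gB_p1", "gB_p2", "gB_p3"], name="probe_id"),
    )


@pytest.fixture()
def toy_annotation():
    return pd.DataFrame(
        {
            "probe_id": ["gA_p1", "gA_p2", "gB_p1", "gB_p2", "gB_p3"],
            "gene_symbol": ["GA", "GA", "GB", "GB", "GB"],
        }
    )
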