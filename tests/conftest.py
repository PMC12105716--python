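import numpy as np
import pandas as pd
import pytest

from circlife.core_io import CountMatrix, SampleSheet


@pytest.fixture
def toy_sheet() -> SampleSheet:
    """6 ages x 3 replicates, one sex (plus a spare sample the matrices omit)."""
    rows = [
        {"sample_id": f"s_age{age}_r{rep}", "age_days": age, "sex": "female",
         "condition": "aging", "replicate": rep, "tissue": "head"}
        for age in (0, 10, 20, 30, 40, 50) for rep in (1, 2, 3)
    ]
    rows.append({"sample_id": "spare", "age_days": 0, "sex": "male",
                 "condition": "aging", "replicate": 1, "tissue": "head"})
    return SampleSheet(pd.DataFrame(rows))


@pytest.fixture
def toy_counts(toy_sheet) -> CountMatrix:
    rng = np.random.default_rng(0)
    samples = [s for s in toy_sheet.sample_ids if s != "spare"]
    values = pd.DataFrame(
        rng.poisson(50, size=(8, len(samples))),
        index=[f"circ{i}" for i in range(8)], columns=samples,
    )
    return CountMatrix(values, kind="circ")


@pytest.fixture(scope="session")
def aging_sim_small():
    """A small deterministic aging simulation shared across tests."""
    from circlife.synthetic_data import SimConfig, simulate_aging

    return simulate_aging(SimConfig(seed=123, n_circ_per_cluster=30))


@pytest.fixture(scope="session")
def genome_fixture():
    from circlife.synthetic_data import make_genome_fixture

    return make_genome_fixture(12, seed=5)
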