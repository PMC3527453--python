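import numpy as np
import pandas as pd
import pytest

from snpcombo import CohortData, Combination, RiskIndicator
from snpcombo.cohort import DELETION_COLUMN, SNP_COLUMNS
from snpcombo.simulate import PlantedEffect, SimulationConfig, simulate_cohort


def make_subject_frame(rows):
    """Build a raw cohort DataFrame from per-subject dicts, filling
    covariates and genotypes with benign defaults."""
    defaults = {"smoking": "non", "age": 60, "gender": "male", "site": "site_A"}
    defaults.update({p: 0 for p in SNP_COLUMNS})
    defaults[DELETION_COLUMN] = "present"
    out = []
    for i, row in enumerate(rows):
        rec = {"id": f"H{i:03d}", **defaults, **row}
        out.append(rec)
    return pd.DataFrame(out)


@pytest.fixture
def hand_cohort():
    """8 subjects with hand-checkable exposure: the combination
    rs9642880 in {1,2} AND rs1014971 == 2 exposes subjects 0-2 and 4."""
    rows = [
        {"status": 1, "rs9642880": 1, "rs1014971": 2},  # exposed case
        {"status": 1, "rs9642880": 2, "rs1014971": 2},  # exposed case
        {"status": 1, "rs9642880": 1, "rs1014971": 2},  # exposed case
        {"status": 1, "rs9642880": 0, "rs1014971": 2},  # unexposed case
        {"status": 0, "rs9642880": 2, "rs1014971": 2},  # exposed control
        {"status": 0, "rs9642880": 1, "rs1014971": 0},  # unexposed control
        {"status": 0, "rs9642880": 0, "rs1014971": 1},  # unexposed control
        {"status": 0, "rs9642880": "NA", "rs1014971": 2},  # undefined exposure
    ]
    from snpcombo import cohort_from_dataframe

    return cohort_from_dataframe(make_subject_frame(rows))


@pytest.fixture
def pair_combination():
    return Combination(
        (RiskIndicator("rs9642880", (1, 2)), RiskIndicator("rs1014971", (2,)))
    )


@pytest.fixture(scope="session")
def planted_config(session_combination):
    return SimulationConfig(
        stratum_sizes={"non": (1000, 1000), "current": (1000, 1000)},
        planted=[PlantedEffect(session_combination, "all", 2.0)],
    )


@pytest.fixture(scope="session")
def session_combination():
    return Combination(
        (RiskIndicator("rs9642880", (1, 2)), RiskIndicator("rs1014971", (2,)))
    )


@pytest.fixture(scope="session")
def planted_cohort(planted_config) -> CohortData:
    """2,000 + 2,000 subjects with a planted two-way conjunction at
    conditional OR 2.0 in every stratum."""
    return simulate_cohort(planted_config, seed=20260928)


@pytest.fixture(scope="session")
def null_cohort() -> CohortData:
    """1,000 + 1,000 subjects with no planted effect."""
    cfg = SimulationConfig(stratum_sizes={"non": (500, 500), "current": (500, 500)})
    return simulate_cohort(cfg, seed=777)
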