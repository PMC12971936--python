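from pathlib import Path

import pandas as pd
import pytest

import pedishape as ps

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def sim_config():
    return ps.default_config(n_subjects=4000)


@pytest.fixture(scope="session")
def bmi_reference(sim_config):
    return ps.derive_bmi_reference(sim_config)


@pytest.fixture(scope="session")
def cohort(sim_config):
    """A moderately sized seeded cohort shared across tests."""
    return ps.simulate_cohort(sim_config, seed=7)


@pytest.fixture(scope="session")
def panel(cohort, bmi_reference):
    """Cohort with the five indices and weight status appended."""
    return ps.BodyShapeIndices(bmi_reference=bmi_reference).fit(cohort).transform(cohort)


@pytest.fixture(scope="session")
def scorer(panel, bmi_reference):
    return ps.CmriScorer(bmi_reference=bmi_reference).fit(panel)


@pytest.fixture(scope="session")
def scored(panel, scorer):
    """Panel with component z-scores, CMRI z and the high-risk flag."""
    return scorer.transform(panel)


@pytest.fixture(scope="session")
def published_reference():
    """Bundled published pediatric BRI/ABSI percentile reference values."""
    return pd.read_csv(DATA_DIR / "published_reference_tables.csv")


@pytest.fixture(scope="session")
def published_screening():
    """Bundled published single-cutoff screening rows (sens/spec/YI/AUC)."""
    return pd.read_csv(DATA_DIR / "published_screening_rows.csv")
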