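import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from bdzscreen.ehr_model import write_dataset
from bdzscreen.reference_catalog import load_catalog
from bdzscreen.synthetic_data import SimConfig, generate, make_case_vignette_fixture


@pytest.fixture(scope="session")
def catalog():
    return load_catalog()


@pytest.fixture(scope="session")
def vignette_data(catalog):
    """Hand-built fixture dataset plus the vignette hospitalization ids."""
    return make_case_vignette_fixture(catalog)


@pytest.fixture(scope="session")
def small_sim(catalog):
    """Seeded ~60-patient simulation with default spike-ins."""
    cfg = SimConfig(seed=20110101, n_patients=60)
    return generate(cfg, catalog), cfg


@pytest.fixture()
def clean_table_dir(tmp_path, vignette_data):
    """The vignette dataset written to canonical CSV files."""
    dataset, _ = vignette_data
    write_dataset(dataset, tmp_path)
    return tmp_path
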