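import numpy as np
import pandas as pd
import pytest

from odoratlas.records import _coerce_dtypes, synonym_table_from_frame
from odoratlas.simulate import SyntheticConfig, generate_database

#: Row defaults for hand-built record tables.
_DEFAULTS = {
    "data_type": "OR",
    "species": "Aedes_aegypti",
    "odorant_canonical": "odorant-000",
    "compound_id": None,
    "concentration_value": 1e-2,
    "concentration_unit": "vv_fraction",
    "response_value": 0.0,
    "response_unit": "spikes/s",
    "technique": "empty_neuron",
    "receptor_or_sensillum": "",
    "assay_category": "",
    "behavioral_context": "",
    "age_days_min": np.nan,
    "age_days_max": np.nan,
    "sex": "",
    "study_id": "study-01",
    "eag_reference": "",
    "background_subtracted": False,
}


def make_records(rows):
    """Build a schema-conformant record table from partial row dicts."""
    return _coerce_dtypes(pd.DataFrame([{**_DEFAULTS, **r} for r in rows]))


@pytest.fixture(scope="session")
def synonym_frame():
    rows = [
        ("3-methyl-1-butanol", "3-methyl-1-butanol", 31260, 88.15),
        ("isoamyl alcohol", "3-methyl-1-butanol", 31260, 88.15),
        ("isopentyl alcohol", "3-methyl-1-butanol", 31260, 88.15),
        ("isopentanol", "3-methyl-1-butanol", 31260, 88.15),
        ("lactic acid", "lactic acid", 612, 90.08),
        ("1-octen-3-ol", "1-octen-3-ol", 18827, 128.21),
        ("benzaldehyde", "benzaldehyde", 240, 106.12),
    ]
    return pd.DataFrame(
        rows, columns=["synonym", "canonical_name", "compound_id", "molecular_weight"]
    )


@pytest.fixture(scope="session")
def synonyms(synonym_frame):
    return synonym_table_from_frame(synonym_frame)


@pytest.fixture(scope="session")
def default_db():
    """One default-sized synthetic database shared across tests."""
    return generate_database(SyntheticConfig(seed=101))


@pytest.fixture(scope="session")
def small_db():
    """A small database for quick structural checks."""
    return generate_database(
        SyntheticConfig(seed=7, n_odorants=40, n_ors=6, n_studies=6)
    )
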