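from importlib import resources
from pathlib import Path

import pytest

from patlas.consensus import Thresholds, load_score_table
from patlas.frequency import read_frequency_table
from patlas.gene_model import load_gene_model
from patlas.phenotype import load_patient_table
from patlas.variants import load_variant_table


def data_path(name: str) -> Path:
    return Path(str(resources.files("patlas.data").joinpath(name)))


@pytest.fixture(scope="session")
def model():
    return load_gene_model()


@pytest.fixture(scope="session")
def reported():
    """The curated 31-site clinical mutation lineage."""
    return load_variant_table(data_path("variants_reported.tsv"))


@pytest.fixture(scope="session")
def database():
    return load_variant_table(data_path("database_variants.tsv"))


@pytest.fixture(scope="session")
def scores():
    return load_score_table()


@pytest.fixture(scope="session")
def thresholds():
    return Thresholds.load()


@pytest.fixture(scope="session")
def patients():
    return load_patient_table(data_path("patients.tsv"))


@pytest.fixture(scope="session")
def freq_reported():
    return read_frequency_table(data_path("frequencies_reported.tsv"))


@pytest.fixture(scope="session")
def freq_database():
    return read_frequency_table(data_path("frequencies_database.tsv"))
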