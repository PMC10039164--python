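import pytest

from cdwquery import EAVStore, SyntheticConfig, build_store, generate_hospital
from cdwquery.clinical import register_clinical_concepts
from cdwquery.dicom import register_imaging_concepts


@pytest.fixture
def store():
    """Empty store with the built-in concept dictionaries registered."""
    s = EAVStore()
    register_clinical_concepts(s)
    register_imaging_concepts(s)
    return s


@pytest.fixture(scope="session")
def hospital():
    """The default synthetic hospital extract (seed 0, 200 patients)."""
    return generate_hospital(SyntheticConfig())


@pytest.fixture(scope="session")
def hospital_store(hospital):
    return build_store(hospital)
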