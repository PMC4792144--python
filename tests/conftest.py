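import pytest

from wrkyfam.classify import ReferenceSet
from wrkyfam.io_formats import load_table1_fixture, load_table2_fixture
from wrkyfam.synthetic_data import make_reference_templates


@pytest.fixture(scope="session")
def table1():
    return load_table1_fixture()


@pytest.fixture(scope="session")
def table2():
    return load_table2_fixture()


@pytest.fixture(scope="session")
def reference_set():
    """Synthetic labeled reference domains, one per group/subgroup label."""
    templates = make_reference_templates()
    return ReferenceSet(entries=tuple(
        (f"ref_{label}", label, seq) for label, seq in templates.items()))
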