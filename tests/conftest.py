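import pytest

from methylight.assay_design import builtin_assays
from methylight.bisulfite_core import four_templates
from methylight.synthetic_fixtures import demo_region, reference_region


@pytest.fixture(scope="session")
def assays():
    """Built-in published assays keyed by name."""
    return {a.name: a for a in builtin_assays()}


@pytest.fixture(scope="session")
def p16_region():
    return demo_region(seed=0)


@pytest.fixture(scope="session")
def p16_templates(p16_region):
    return four_templates(p16_region)


@pytest.fixture(scope="session")
def col2a1_region():
    return reference_region(seed=0)


@pytest.fixture(scope="session")
def col2a1_templates(col2a1_region):
    return four_templates(col2a1_region)
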