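import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from ctoscores.synthetic import CohortConfig, fixture_table2_cohort, generate_cohort


@pytest.fixture(scope="session")
def table2_cohort():
    """The deterministic 110-lesion reference cohort."""
    return fixture_table2_cohort()


@pytest.fixture(scope="session")
def small_cohort():
    """A 300-lesion synthetic cohort with default associations."""
    return generate_cohort(CohortConfig(n_lesions=300, seed=11))
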