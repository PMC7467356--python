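import numpy as np
import pytest

import igglycome as ig


@pytest.fixture(scope="session")
def small_cohort():
    """Two-country cohort used by quantification round-trip tests."""
    design = ig.CohortDesign(
        countries=[ig.CountrySpec("A", 20), ig.CountrySpec("B", 20)], seed=1)
    return ig.simulate_cohort(design)


@pytest.fixture(scope="session")
def medium_cohort():
    """Cohort with enough countries/samples for modelling-stage tests."""
    design = ig.CohortDesign(
        countries=[ig.CountrySpec(f"C{i}", 60) for i in range(8)], seed=2)
    return ig.simulate_cohort(design)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
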