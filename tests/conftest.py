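import numpy as np
import pytest

from bff import TestReport
from bff.examples import fixture_confirmatory_studies, fixture_table2


@pytest.fixture
def z_report() -> TestReport:
    """The one-sample z example: z = 2 observed with n = 100."""
    return TestReport(family="z", statistic=2.0, n=100, design="one_sample")


@pytest.fixture
def cancer_table():
    """4x3 site-by-blood-group contingency table, 707 patients."""
    return fixture_table2()


@pytest.fixture
def confirmatory_studies():
    """Original + replication one-way ANOVA F statistics."""
    return fixture_confirmatory_studies()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230213)
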