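import numpy as np
import pytest

from spscan.contingency import StratifiedTable, StratumTable
from spscan.regress import BivariateSample


@pytest.fixture
def berkeley() -> StratifiedTable:
    """Stylized two-faculty admission table (males x accepted)."""
    return StratifiedTable(
        (
            StratumTable("Faculty A", 820, 80, 680, 20),
            StratumTable("Faculty B", 20, 80, 100, 200),
        )
    )


@pytest.fixture
def four_points() -> BivariateSample:
    """Tiny hand-checkable regression fixture: slope 0.8, intercept 0.3."""
    return BivariateSample(x=[0, 1, 2, 3], y=[0, 2, 1, 3])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260925)
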