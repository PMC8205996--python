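from decimal import Decimal

import pytest

from arvcurate.matrix import default_matrix
from arvcurate.synthetic import arvc_fixture


@pytest.fixture(scope="session")
def matrix():
    return default_matrix()


@pytest.fixture(scope="session")
def fixture():
    return arvc_fixture()


def D(x) -> Decimal:
    return Decimal(str(x))
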