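import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for _oracles

from rptdose import load_chain


@pytest.fixture(scope="session")
def lu_chain():
    return load_chain("Lu-177")


@pytest.fixture(scope="session")
def ac_chain():
    return load_chain("Ac-225")
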