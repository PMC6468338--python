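import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # expected_uganda, oracle

from crcpse import estimate_all, load_uganda_summaries


@pytest.fixture(scope="session")
def uganda_summaries():
    return load_uganda_summaries()


@pytest.fixture(scope="session")
def uganda_by_key(uganda_summaries):
    return {(s.population, s.town): s for s in uganda_summaries}


@pytest.fixture(scope="session")
def uganda_estimates(uganda_summaries):
    estimates, not_estimable = estimate_all(uganda_summaries)
    assert not not_estimable
    return {(e.population, e.town, e.definition): e for e in estimates}
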