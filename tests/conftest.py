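import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))


@pytest.fixture(scope="session")
def two_channel_chain():
    """One shared chain run on the two-channel fixture (expensive)."""
    from qtps.experiments import fixture_chain

    prob, profile, record = fixture_chain("two_channel", n_steps=2600, seed=1)
    return prob, profile, record
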