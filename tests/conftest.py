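import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from micropat import synthetic as syn  # noqa: E402


@pytest.fixture
def two_day_meta():
    """Small two-timepoint design: 4 mice per sex x treatment cell."""
    return syn.generate_metadata(4, [12, 42], seed=11)


@pytest.fixture
def single_day_meta():
    """Cross-sectional design used by the association-network stage."""
    return syn.generate_metadata(6, [23], seed=12)
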