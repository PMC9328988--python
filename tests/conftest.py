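import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from _oracles import build_ds  # noqa: E402

from wbbn.dataio import wbc_schema  # noqa: E402


@pytest.fixture(scope="session")
def schema_wbc():
    return wbc_schema()


@pytest.fixture()
def toy_ds():
    """10 records over 2 binary attributes: att1 bin 1 occurs in 3 positive
    and 2 negative records (joint weight 0.3, posterior weight 0.6)."""
    rows = [
        (1, 0, 1),
        (1, 1, 1),
        (1, 0, 1),
        (1, 1, 0),
        (1, 0, 0),
        (0, 1, 1),
        (0, 0, 0),
        (0, 1, 0),
        (0, 0, 0),
        (0, 1, 0),
    ]
    return build_ds(2, rows)
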