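import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_gmt(tmp_path):
    """Two-term GMT file over a five-gene universe."""
    path = tmp_path / "sets.gmt"
    path.write_text(
        "term_a\tdesc\tG1\tG2\tG3\n"
        "term_b\tdesc\tG1\tG4\tG5\tG2\tG3\n"
    )
    return path
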