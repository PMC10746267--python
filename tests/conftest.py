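import numpy as np
import pytest

from acidae.containers import ExpressionCompendium


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_compendium():
    """3 genes x 6 samples, two conditions, known values."""
    values = np.array([
        [5.0, 5.2, 4.8, 8.0, 8.1, 7.9],   # induced under acid
        [6.0, 6.1, 5.9, 6.0, 6.2, 5.8],   # flat
        [3.0, 3.1, 2.9, 2.0, 2.1, 1.9],   # repressed under acid
    ])
    sample_ids = [f"control_rep{i}" for i in (1, 2, 3)] + [f"acid_rep{i}" for i in (1, 2, 3)]
    cond = {s: ("control" if s.startswith("control") else "acid") for s in sample_ids}
    return ExpressionCompendium(values, ["gA", "gB", "gC"], sample_ids, cond)
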