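import numpy as np
import pytest

from degronmps.synthetic import DegronRule, GroundTruthModel


@pytest.fixture
def phin_model():
    """Minimal ground truth: a single strictly C-terminal ΦN rule."""
    rule = DegronRule(
        "phiN", 0.8, neutralized_by=frozenset({"das1"}),
        position_sets={-2: frozenset("ILMV"), -1: frozenset("N")},
    )
    return GroundTruthModel([rule], baseline_stability=0.9, cell_noise_sd=0.1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
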