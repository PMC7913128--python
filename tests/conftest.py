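import numpy as np
import pytest
from hypothesis import settings

from moscreen.desirability import ProbabilityMatrix

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture
def tiny_matrix() -> ProbabilityMatrix:
    """6 compounds x 4 columns (3 targets, 1 off-target); c0/c1 desirable."""
    P = np.array(
        [
            [0.9, 0.8, 0.7, 0.1],
            [0.8, 0.9, 0.6, 0.2],
            [0.2, 0.3, 0.4, 0.8],
            [0.1, 0.2, 0.5, 0.9],
            [0.5, 0.5, 0.5, 0.5],
            [0.3, 0.1, 0.2, 0.7],
        ]
    )
    return ProbabilityMatrix(
        P=P,
        compound_ids=tuple(f"c{i}" for i in range(6)),
        target_ids=("T0", "T1", "T2", "O0"),
        roles=np.array(["target", "target", "target", "off_target"],
                       dtype=object),
        actives=frozenset({"c0", "c1"}),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
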