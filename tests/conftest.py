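import numpy as np
import pytest

from nodalstage import ModelConfig, NodalPrior, invert_table, reference_cells


@pytest.fixture(scope="session")
def config() -> ModelConfig:
    return ModelConfig()


@pytest.fixture(scope="session")
def t1_cells():
    """Published T1 accuracy cells (n = 4..14, m = 1..3)."""
    return reference_cells("T1", "accuracy")


@pytest.fixture(scope="session")
def t1_prior(t1_cells) -> NodalPrior:
    """T1 prior recovered from the full published accuracy table."""
    return invert_table(t1_cells, stage_label="T1")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def random_prior(
    rng: np.random.Generator,
    total_nodes: int = 15,
    support: tuple[int, int] | None = None,
    stage_label: str = "random",
) -> NodalPrior:
    """Dirichlet prior restricted to a support window (inclusive)."""
    lo, hi = support if support is not None else (0, total_nodes)
    probs = np.zeros(total_nodes + 1)
    probs[lo : hi + 1] = rng.dirichlet(np.ones(hi - lo + 1))
    return NodalPrior(stage_label=stage_label, probs=probs)
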