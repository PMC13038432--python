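import numpy as np
import pytest

from excluscope import InstrumentSet
from excluscope.io import load_candidate_metrics


@pytest.fixture(scope="session")
def candidate_metrics():
    """The bundled five-gene candidate MR/SMR metrics fixture."""
    return load_candidate_metrics()


def random_instrument_set(
    n: int = 20, seed: int = 0, true_beta: float = 0.1, gene: str = "g"
) -> InstrumentSet:
    """A quick harmonized instrument set with a known causal effect."""
    rng = np.random.default_rng(seed)
    bx = rng.uniform(0.1, 0.5, n) * rng.choice([-1, 1], n)
    se_x = np.full(n, 0.01)
    se_y = rng.uniform(0.005, 0.02, n)
    by = true_beta * bx + se_y * rng.standard_normal(n)
    return InstrumentSet(
        gene=gene,
        snp_ids=[f"rs{j:04d}" for j in range(n)],
        beta_exp=bx.tolist(),
        se_exp=se_x.tolist(),
        beta_out=by.tolist(),
        se_out=se_y.tolist(),
    )


@pytest.fixture
def iset20():
    return random_instrument_set(20, seed=7)
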