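import warnings

import numpy as np
import pytest

from tlinet import FusionParams, fasta_to_graph, split
from tlinet.curriculum import DESK_BATCH_SIZE, StageConfig, run_curriculum
from tlinet.gcn import DESK_CONFIG
from tlinet.synth import FixtureSpec, generate_benchmark

warnings.filterwarnings("ignore", message="tied scores present")


@pytest.fixture(scope="session")
def small_benchmark():
    """Deterministic 20-active / 20-decoy easy benchmark."""
    return generate_benchmark(FixtureSpec(n_actives=20, n_decoys=20, seed=7))


@pytest.fixture(scope="session")
def desk_params():
    """Randomly initialized desk-scale fusion parameters."""
    return FusionParams(DESK_CONFIG, rng=0)


@pytest.fixture(scope="session")
def trained_lm(small_benchmark):
    """A ligand module briefly trained on the small benchmark.

    Provides non-trivial gradients and predictions for augmentation and
    saliency tests without repeating the full curriculum.
    """
    ds = split(small_benchmark.dataset, seed=0)
    protein = fasta_to_graph(small_benchmark.protein_sequence)
    params, reports = run_curriculum(
        ds,
        protein,
        stages=[StageConfig("LM", epochs=25, learning_rate=5e-3)],
        seed=0,
        batch_size=DESK_BATCH_SIZE,
    )
    return {
        "params": params,
        "dataset": ds,
        "benchmark": small_benchmark,
        "protein": protein,
        "reports": reports,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
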