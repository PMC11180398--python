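import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from ddirisk.graph import DDIEvent, DrugRecord  # noqa: E402
from ddirisk.synthetic import SyntheticConfig, generate_network  # noqa: E402
from ddirisk.train import TrainConfig  # noqa: E402


@pytest.fixture(scope="session")
def toy_drugs() -> list[DrugRecord]:
    smiles = ["CCO", "c1ccccc1", "CC(=O)O", "CCN", "ClCCCl", "C1CCCCC1"]
    return [DrugRecord(f"D{i}", s) for i, s in enumerate(smiles)]


@pytest.fixture(scope="session")
def toy_events() -> list[DDIEvent]:
    return [DDIEvent("D0", "D1", 0), DDIEvent("D1", "D2", 1),
            DDIEvent("D2", "D3", 2), DDIEvent("D3", "D4", 3),
            DDIEvent("D0", "D5", 1), DDIEvent("D1", "D5", 2)]


@pytest.fixture(scope="session")
def small_network():
    """A small feature-determined network used by training-path tests."""
    cfg = SyntheticConfig(n_drugs=60, n_relations=4,
                          class_proportions=(0.25, 0.25, 0.25, 0.25),
                          feature_label_coupling=1.0, n_clusters=4,
                          edge_density=0.12, seed=42)
    drugs, events, truth = generate_network(cfg)
    return drugs, events, truth


@pytest.fixture
def fast_config() -> TrainConfig:
    """Small, quick training configuration for functional tests."""
    return TrainConfig(epochs=25, learning_rate=5e-3, feature_dim=16,
                       hidden=16, n_heads=4, attn_batch_size=64, seed=0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
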