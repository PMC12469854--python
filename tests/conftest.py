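import numpy as np
import pytest

from senosynergy.feature_fusion import CellLineProfile, DrugRecord, FeatureSpace
from senosynergy.geneset_assembly import GeneUniverse
from senosynergy.synergy_model import ModelConfig
from senosynergy.synthetic_data import SyntheticConfig, gen_combos, gen_world


@pytest.fixture
def small_universe() -> GeneUniverse:
    return GeneUniverse.from_ids([f"g{i}" for i in range(1, 7)])


@pytest.fixture
def small_world():
    cfg = SyntheticConfig(
        n_genes=20, n_drugs=8, targets_per_drug_mean=4, n_cell_lines=3,
        module_size=5, n_combos=60, seed=11,
    )
    return gen_world(cfg)


@pytest.fixture
def small_combos(small_world):
    return gen_combos(small_world)


@pytest.fixture
def small_features(small_world) -> FeatureSpace:
    return FeatureSpace(small_world.drugs, small_world.cells, small_world.universe)


@pytest.fixture
def tiny_model_config() -> ModelConfig:
    # scaled-down architecture for fast unit tests; contracts are size-independent
    return ModelConfig(
        d_model=16, n_heads=4, head_hidden=(8, 4), dropout=0.3,
        batch_size=16, max_epochs=5, patience=3, val_fraction=0.2, seed=5,
    )


@pytest.fixture
def toy_drugs(small_universe):
    g = small_universe.genes
    return {
        "a": DrugRecord("a", {g[0], g[1]}),
        "b": DrugRecord("b", {g[1], g[2]}),
        "c": DrugRecord("c", set(g)),
    }


@pytest.fixture
def toy_cell(small_universe):
    rng = np.random.default_rng(3)
    return CellLineProfile("toy", rng.normal(size=len(small_universe)))
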