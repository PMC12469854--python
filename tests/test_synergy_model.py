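import numpy as np
import pytest

from senosynergy.combo_pipeline import ComboRecord
from senosynergy.synergy_model import (
    EarlyStopper,
    ModelConfig,
    SynergyModel,
    build_model,
    predict_pair,
    train,
)


class TestModelConfig:
    def test_defaults(self):
        c = ModelConfig()
        assert c.d_model == 128 and c.n_heads == 8 and c.n_blocks == 2
        assert c.head_hidden == (256, 128) and c.dropout == 0.3
        assert c.learning_rate == 0.003 and c.batch_size == 128
        assert c.max_epochs == 100 and c.patience == 10

    def test_divisibility(self):
        with pytest.raises(ValueError):
            ModelConfig(d_model=100, n_heads=8)

    def test_dropout_range(self):
        with pytest.raises(ValueError):
            ModelConfig(dropout=1.0)

    def test_patience_bound(self):
        with pytest.raises(ValueError):
            ModelConfig(patience=200, max_epochs=100)


class TestEarlyStopper:
    def test_worked_trace(self):
        # losses [3.0, 2.0, 2.5, 2.6] with patience 2 -> stop at epoch 4, best 2
        s = EarlyStopper(patience=2)
        stops = [s.update(e, v) for e, v in enumerate([3.0, 2.0, 2.5, 2.6], 1)]
        assert stops == [False, False, False, True]
        assert s.best_epoch == 2

    def test_strict_improvement_required(self):
        s = EarlyStopper(patience=1)
        assert not s.update(1, 1.0)
        assert s.update(2, 1.0)  # equal loss is not an improvement


class TestBuildModel:
    def test_output_shape_and_finite(self, tiny_model_config):
        m = build_model(tiny_model_config, universe_size=7)
        X = np.random.default_rng(0).normal(size=(5, 21))
        y, _ = m.forward(X)
        assert y.shape == (5,)
        assert np.all(np.isfinite(y))

    def test_eval_forward_bit_identical(self, tiny_model_config):
        m = build_model(tiny_model_config, universe_size=7)
        X = np.random.default_rng(0).normal(size=(3, 21))
        y1, _ = m.forward(X)
        y2, _ = m.forward(X)
        assert y1.tobytes() == y2.tobytes()

    def test_same_seed_same_init(self, tiny_model_config):
        X = np.random.default_rng(1).normal(size=(4, 21))
        y1, _ = build_model(tiny_model_config, 7).forward(X)
        y2, _ = build_model(tiny_model_config, 7).forward(X)
        assert np.array_equal(y1, y2)

    def test_zero_universe_rejected(self, tiny_model_config):
        with pytest.raises(ValueError):
            build_model(tiny_model_config, 0)

    def test_row_width_checked(self, tiny_model_config):
        m = build_model(tiny_model_config, 7)
        with pytest.raises(ValueError, match="width"):
            m.forward(np.zeros((2, 20)))


class TestTrain:
    def test_histories_reproducible(self, small_world, small_combos, small_features,
                                    tiny_model_config):
        runs = []
        for _ in range(2):
            model = build_model(tiny_model_config, len(small_world.universe))
            _, hist = train(model, small_combos.records, small_features, tiny_model_config)
            runs.append(hist)
        assert runs[0].train_mse == runs[1].train_mse
        assert runs[0].val_mse == runs[1].val_mse
        assert runs[0].best_epoch == runs[1].best_epoch

    def test_trained_weights_reproducible(self, small_world, small_combos,
                                          small_features, tiny_model_config):
        models = []
        for _ in range(2):
            m = build_model(tiny_model_config, len(small_world.universe))
            train(m, small_combos.records, small_features, tiny_model_config)
            models.append(m)
        for k in models[0].params:
            assert models[0].params[k].tobytes() == models[1].params[k].tobytes()

    def test_best_val_is_min_and_weights_restored(self, small_world, small_combos,
                                                  small_features, tiny_model_config):
        model = build_model(tiny_model_config, len(small_world.universe))
        model, hist = train(model, small_combos.records, small_features, tiny_model_config)
        assert hist.best_epoch <= hist.stopped_epoch <= tiny_model_config.max_epochs
        assert hist.val_mse[hist.best_epoch - 1] == min(hist.val_mse)

    def test_constant_labels_learn_mean(self, small_world, small_features):
        cfg = ModelConfig(d_model=16, n_heads=4, head_hidden=(8, 4), dropout=0.0,
                          batch_size=16, max_epochs=150, patience=150,
                          val_fraction=0.2, seed=2, learning_rate=0.02)
        const = 5.0
        combos = [
            ComboRecord(c.drugA, c.drugB, c.cell_line, const)
            for c in __import__("senosynergy").synthetic_data.gen_combos(small_world).records
        ]
        model = build_model(cfg, len(small_world.universe))
        model, _ = train(model, combos, small_features, cfg)
        c0 = combos[0]
        pred = predict_pair(
            model, small_world.drugs[c0.drugA], small_world.drugs[c0.drugB],
            small_world.cells[c0.cell_line], small_world.universe,
        )
        assert abs(pred - const) < 0.5

    def test_too_few_combos(self, small_world, small_features, tiny_model_config):
        c = ComboRecord("drug-000", "drug-001", "cell-00", 1.0)
        model = build_model(tiny_model_config, len(small_world.universe))
        with pytest.raises(ValueError):
            train(model, [c], small_features, tiny_model_config)

    def test_empty_validation_split(self, small_world, small_features):
        cfg = ModelConfig(d_model=16, n_heads=4, head_hidden=(8, 4),
                          val_fraction=0.1, seed=1)
        combos = [
            ComboRecord("drug-000", "drug-001", "cell-00", 1.0),
            ComboRecord("drug-000", "drug-002", "cell-00", 1.0),
        ]  # 2 combos * 0.1 -> zero validation rows
        model = build_model(cfg, len(small_world.universe))
        with pytest.raises(ValueError, match="larger dataset"):
            train(model, combos, small_features, cfg)


class TestPredict:
    @pytest.fixture
    def trained(self, small_world, small_combos, small_features, tiny_model_config):
        model = build_model(tiny_model_config, len(small_world.universe))
        model, _ = train(model, small_combos.records, small_features, tiny_model_config)
        return model

    def test_exact_order_symmetry(self, trained, small_world):
        d = small_world.drugs
        cell = small_world.cells["cell-00"]
        ab = predict_pair(trained, d["drug-000"], d["drug-001"], cell, small_world.universe)
        ba = predict_pair(trained, d["drug-001"], d["drug-000"], cell, small_world.universe)
        assert ab == ba

    def test_identical_drugs_mean_equals_single_pass(self, trained, small_world):
        d = small_world.drugs["drug-000"]
        cell = small_world.cells["cell-00"]
        from senosynergy.feature_fusion import fuse

        X = trained.standardizer.transform(
            fuse(d, d, cell, small_world.universe)[None, :]
        )
        single = float(trained.predict_rows(X)[0])
        assert predict_pair(trained, d, d, cell, small_world.universe) == pytest.approx(single)

    def test_unfitted_standardizer_rejected(self, small_world, tiny_model_config):
        model = build_model(tiny_model_config, len(small_world.universe))
        d = small_world.drugs
        with pytest.raises(RuntimeError, match="standardizer"):
            predict_pair(model, d["drug-000"], d["drug-001"],
                         small_world.cells["cell-00"], small_world.universe)


class TestPersistence:
    def test_save_load_roundtrip(self, small_world, small_combos, small_features,
                                 tiny_model_config, tmp_path):
        model = build_model(tiny_model_config, len(small_world.universe))
        model, _ = train(model, small_combos.records, small_features, tiny_model_config)
        path = tmp_path / "model.npz"
        model.save(path)
        loaded = SynergyModel.load(path)
        d = small_world.drugs
        cell = small_world.cells["cell-01"]
        assert predict_pair(loaded, d["drug-002"], d["drug-003"], cell,
                            small_world.universe) == pytest.approx(
            predict_pair(model, d["drug-002"], d["drug-003"], cell, small_world.universe)
        )
        assert loaded.universe_hash == model.universe_hash
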