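"""Route architectures: symbolic shape traces and parameter counts against
the reference tables, and the training harness contracts."""

import numpy as np
import pytest

from mvmdm import models
from mvmdm.models import (
    ModelSpec,
    ParamCount,
    TrainConfig,
    classify,
    kfold_evaluate,
    model_spec,
    parameter_count,
    shape_trace,
    train,
)


class TestReferenceArchitectures:
    def test_conv1d_trace(self):
        spec = model_spec("conv1d_energy")
        assert spec.input_shape == (88, 1)
        assert len(spec.layers) == 7
        assert shape_trace(spec) == [
            (86, 32), (43, 32), (41, 64), (20, 64), (1280,), (64,), (1,),
        ]

    def test_conv2d_trace_and_structure(self):
        spec = model_spec("conv2d_fused")
        kinds = [l.kind for l in spec.layers]
        assert kinds.count("batchnorm") == 3
        assert any(l.kind == "dropout" and l.rate == 0.2 for l in spec.layers)
        trace = shape_trace(spec)
        assert trace[8] == (14, 14, 128)
        assert trace[9] == (25088,)  # 14 * 14 * 128
        assert trace[-1] == (1,)

    def test_conv3d_trace(self):
        spec = model_spec("conv3d_volume")
        kinds = [l.kind for l in spec.layers]
        assert kinds.count("conv3d") == 4 and kinds.count("maxpool3d") == 4
        trace = shape_trace(spec)
        assert trace[0] == (87, 126, 126, 32)
        assert trace[7] == (84, 6, 6, 64)
        assert trace[8] == (193536,)

    @pytest.mark.parametrize(
        "kind,total,trainable,non_trainable",
        [
            ("conv1d_energy", 88_385, 88_385, 0),
            ("conv2d_fused", 3_305_089, 3_304_641, 448),
            ("conv3d_volume", 24_957_985, 24_957_985, 0),
        ],
    )
    def test_parameter_counts(self, kind, total, trainable, non_trainable):
        pc = parameter_count(model_spec(kind))
        assert (pc.total, pc.trainable, pc.non_trainable) == (total, trainable, non_trainable)

    def test_final_layer_is_single_sigmoid_unit(self):
        for kind in models.MODEL_KINDS:
            last = model_spec(kind).layers[-1]
            assert last.kind == "dense" and last.units == 1 and last.activation == "sigmoid"

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown model kind"):
            model_spec("conv4d")

    def test_built_network_parameter_count_matches_symbolic(self):
        """The engine's actual arrays carry exactly the traced counts."""
        spec = model_spec("conv1d_energy")
        net = models.build_network(spec, seed=0)
        n_params = sum(p.size for layer in net.layers for p in layer.params)
        assert n_params == parameter_count(spec).total

    def test_scaled_inputs_keep_pattern_and_positive_trace(self):
        spec1 = model_spec("conv1d_energy", input_shape=(16, 1))
        assert shape_trace(spec1)[-1] == (1,)
        spec3 = model_spec("conv3d_volume", input_shape=(16, 32, 32, 1))
        kinds = [l.kind for l in spec3.layers]
        assert 1 <= kinds.count("conv3d") < 4  # trailing blocks dropped
        assert all(all(d > 0 for d in s) for s in shape_trace(spec3))

    def test_paramcount_consistency_enforced(self):
        with pytest.raises(ValueError):
            ParamCount(total=10, trainable=5, non_trainable=4)


class TestTrainConfig:
    def test_reference_defaults(self):
        cfg = TrainConfig()
        assert (cfg.optimizer, cfg.learning_rate, cfg.epochs, cfg.batch_size, cfg.k_folds) == (
            "adam", 0.001, 20, 32, 5,
        )

    @pytest.mark.parametrize("kwargs", [{"threshold": 1.0}, {"threshold": 0.0}, {"k_folds": 1}, {"epochs": -1}])
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            TrainConfig(**kwargs)


@pytest.fixture(scope="module")
def toy_energy_data():
    """Linearly separable 1D-route features: (n, 16, 1)."""
    rng = np.random.default_rng(13)
    n = 40
    y = np.arange(n) % 2
    base = rng.normal(size=(n, 16))
    x = base + (1 - y)[:, None] * 3.0
    return x[..., None].astype(np.float32), y


class TestTrainClassify:
    def test_shape_mismatch_rejected(self, toy_energy_data):
        x, y = toy_energy_data
        spec = model_spec("conv1d_energy", input_shape=(24, 1))
        with pytest.raises(ValueError, match="does not match"):
            train(spec, x, y, TrainConfig(epochs=1))

    def test_same_seed_identical_history(self, toy_energy_data):
        x, y = toy_energy_data
        spec = model_spec("conv1d_energy", input_shape=(16, 1))
        cfg = TrainConfig(epochs=4, seed=9)
        _, h1 = train(spec, x, y, cfg)
        _, h2 = train(spec, x, y, cfg)
        assert h1 == h2

    def test_threshold_semantics(self, toy_energy_data):
        x, y = toy_energy_data
        spec = model_spec("conv1d_energy", input_shape=(16, 1))
        net, _ = train(spec, x, y, TrainConfig(epochs=10, seed=1))
        pred, prob = classify(net, x, threshold=0.5)
        np.testing.assert_array_equal(pred, (prob >= 0.5).astype(int))
        # a probability marginally above threshold still votes positive
        assert classify(net, x, threshold=0.51)[0].shape == y.shape
        with pytest.raises(ValueError, match="threshold"):
            classify(net, x, threshold=1.0)

    def test_epochs_zero_gives_empty_history(self, toy_energy_data):
        x, y = toy_energy_data
        spec = model_spec("conv1d_energy", input_shape=(16, 1))
        _, hist = train(spec, x, y, TrainConfig(epochs=0))
        assert hist["loss"] == []


class TestKFold:
    def test_perfectly_separable_folds_and_determinism(self, toy_energy_data):
        x, y = toy_energy_data
        spec = model_spec("conv1d_energy", input_shape=(16, 1))
        cfg = TrainConfig(epochs=10, k_folds=5)
        folds1, summary1 = kfold_evaluate(x, y, spec, cfg, seeds=[41, 42])
        folds2, _ = kfold_evaluate(x, y, spec, cfg, seeds=[41, 42])
        assert folds1.equals(folds2)
        assert len(folds1) == 10  # 2 seeds x 5 folds
        assert (summary1["mean_accuracy"] >= 0.9).all()

    def test_fewer_subjects_than_folds_rejected(self):
        x = np.zeros((6, 16, 1), dtype=np.float32)
        y = np.array([0, 0, 0, 1, 1, 1])
        spec = model_spec("conv1d_energy", input_shape=(16, 1))
        with pytest.raises(ValueError, match="fewer than k_folds"):
            kfold_evaluate(x, y, spec, TrainConfig(k_folds=5, epochs=1), seeds=[1])
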