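"""CNN / DAG-CNN architectures, training contract, activation access."""

import dataclasses

import numpy as np
import pytest

from tlemri.datatypes import LabeledDataset
from tlemri.exceptions import ArchitectureError, ClassBalanceError, ShapeError
from tlemri.models import (
    CNNClassifier,
    CNNSpec,
    DAGClassifier,
    DAGSpec,
    TrainConfig,
    TrainedModel,
    parameter_count,
    stage_shapes,
)
from tlemri.smote import SmoteConfig, balance
from tlemri.synthetic import EffectConfig, generate_cohort

from .conftest import strong_cohort_config


class TestArchitecture:
    def test_output_size_recurrence(self):
        shapes = stage_shapes(CNNSpec(conv_layers=((40, 20), (10, 10), (15, 20))), (4000, 4000))
        assert [(h, w) for _, h, w in shapes] == [(200, 200), (20, 20), (1, 1)]

    def test_single_stage_arithmetic(self):
        shapes = stage_shapes(CNNSpec(conv_layers=((8, 20), (4, 2), (4, 3))), (120, 120))
        assert shapes[0] == (8, 6, 6)  # (120 - 20)/20 + 1

    def test_kernel_chain_overflow_raises_at_offending_layer(self):
        with pytest.raises(ArchitectureError, match="layer 2"):
            stage_shapes(CNNSpec(conv_layers=((8, 20), (8, 10), (8, 20))), (100, 100))

    def test_default_specs_build_on_large_inputs(self):
        # pure arithmetic: no arrays are allocated at build time
        CNNClassifier(CNNSpec(), (4000, 4000))
        DAGClassifier(DAGSpec(), (6750, 6750))

    def test_invalid_specs_rejected(self):
        with pytest.raises(ArchitectureError):
            CNNSpec(conv_layers=((8, 4), (8, 2)))  # only two stages
        with pytest.raises(ArchitectureError):
            CNNSpec(conv_layers=((8, 1), (8, 2), (8, 2)))  # kernel < 2

    @pytest.mark.parametrize("builder, spec_cls", [
        (CNNClassifier, CNNSpec), (DAGClassifier, DAGSpec),
    ])
    def test_parameter_count_closed_form_matches_arrays(self, builder, spec_cls):
        spec = spec_cls.scaled()
        model = builder(spec, (64, 64))
        net = model._make_net(np.random.default_rng(0))
        assert net.n_params == parameter_count(spec, (64, 64))

    def test_dag_merge_shape_equals_conv3_shape(self, strong_cohort, fast_train_cfg):
        ds = strong_cohort.subset(range(0, 50, 3))
        trained = DAGClassifier(DAGSpec.scaled(), (64, 64)).fit(ds, None, fast_train_cfg)
        add = trained.layer_activations(ds.images[0], "addition")
        conv3 = trained.layer_activations(ds.images[0], 3)
        assert add.shape == conv3.shape

    def test_zeroed_skip_branch_reduces_dag_to_cnn(self):
        rng = np.random.default_rng(0)
        x = rng.random((4, 64, 64))
        dag = DAGClassifier(DAGSpec.scaled(), (64, 64))._make_net(np.random.default_rng(1))
        cnn = CNNClassifier(CNNSpec.scaled(), (64, 64))._make_net(np.random.default_rng(2))
        for src, dst in zip(dag.conv_layers, cnn.conv_layers):
            dst.W, dst.b = src.W.copy(), src.b.copy()
        cnn.dense.W, cnn.dense.b = dag.dense.W.copy(), dag.dense.b.copy()
        dag.Wp = np.zeros_like(dag.Wp)
        assert np.allclose(dag.forward(x), cnn.forward(x))


class TestTraining:
    def test_same_seed_gives_identical_parameters(self, strong_cohort, fast_train_cfg):
        ds = strong_cohort.subset(range(0, 50, 2))
        a = CNNClassifier(CNNSpec.scaled(), (64, 64)).fit(ds, None, fast_train_cfg)
        b = CNNClassifier(CNNSpec.scaled(), (64, 64)).fit(ds, None, fast_train_cfg)
        for pa, pb in zip(a.net.get_params(), b.net.get_params()):
            assert np.array_equal(pa, pb)

    def test_single_class_training_rejected(self, strong_cohort, fast_train_cfg):
        hc_only = strong_cohort.subset(np.flatnonzero(strong_cohort.labels == 0))
        with pytest.raises(ClassBalanceError):
            CNNClassifier(CNNSpec.scaled(), (64, 64)).fit(hc_only, None, fast_train_cfg)

    def test_separable_cohort_reaches_high_validation_accuracy(
        self, strong_cohort, fast_train_cfg
    ):
        train = strong_cohort.subset(range(0, 50, 2))
        val = strong_cohort.subset(range(1, 50, 2))
        balanced, _ = balance(train, SmoteConfig(seed=0))
        trained = CNNClassifier(CNNSpec.scaled(), (64, 64)).fit(balanced, val, fast_train_cfg)
        assert trained.history["val_accuracy"].dropna().iloc[-1] >= 0.95

    def test_history_length_follows_validation_frequency(self, strong_cohort):
        ds = strong_cohort.subset(range(0, 50, 3))
        cfg = TrainConfig(learning_rate=0.05, epochs=12, validation_frequency=4, seed=0)
        trained = CNNClassifier(CNNSpec.scaled(), (64, 64)).fit(ds, ds, cfg)
        assert len(trained.history) == 12
        assert trained.history["val_accuracy"].notna().sum() == 3

    def test_loss_decreases_on_noiseless_separable_fixture(self, template64):
        # full-batch plain gradient descent: the loss curve itself must be
        # monotone (mini-batch + momentum only wiggles around it)
        cfg_cohort = strong_cohort_config(effect=0.5, noise_sd=0.0, jitter=0)
        ds = generate_cohort(template64, cfg_cohort, seed=0)
        cfg = TrainConfig(
            learning_rate=0.05, epochs=10, validation_frequency=5, seed=0,
            batch_size=len(ds), momentum=0.0,
        )
        trained = CNNClassifier(CNNSpec.scaled(), (64, 64)).fit(ds, None, cfg)
        loss = trained.history["loss"].to_numpy()
        assert loss[-1] < loss[0]
        assert np.all(np.diff(loss) <= 1e-6)

    def test_permuted_labels_give_chance_level_validation(self, strong_cohort):
        from tlemri.evaluation import _permute_labels

        rng = np.random.default_rng(3)
        train = _permute_labels(strong_cohort.subset(range(0, 50, 2)), rng)
        val = strong_cohort.subset(range(1, 50, 2))
        cfg = TrainConfig(learning_rate=0.05, epochs=15, validation_frequency=15, seed=0)
        trained = CNNClassifier(CNNSpec.scaled(), (64, 64)).fit(train, val, cfg)
        acc = trained.history["val_accuracy"].dropna().iloc[-1]
        majority = max(np.bincount(val.labels)) / len(val)
        assert abs(acc - majority) < 0.3  # within the broad null band


class TestPrediction:
    @pytest.fixture(scope="class")
    def trained(self, strong_cohort, fast_train_cfg):
        train = strong_cohort.subset(range(0, 50, 2))
        balanced, _ = balance(train, SmoteConfig(seed=0))
        return CNNClassifier(CNNSpec.scaled(), (64, 64)).fit(balanced, None, fast_train_cfg)

    def test_scores_are_probabilities(self, trained, strong_cohort):
        scores = trained.predict_scores(strong_cohort)
        assert np.all((scores >= 0) & (scores <= 1))

    def test_duplicated_input_scores_identically(self, trained, strong_cohort):
        im = strong_cohort.images[0]
        twice = trained.predict_scores([im, im])
        assert twice[0] == twice[1]

    def test_patients_score_above_controls_on_separable_fixture(
        self, trained, strong_cohort
    ):
        val = strong_cohort.subset(range(1, 50, 2))
        scores = trained.predict_scores(val)
        labels = val.labels
        assert scores[labels == 1].mean() > scores[labels == 0].mean()

    def test_shape_mismatch_rejected(self, trained):
        with pytest.raises(ShapeError):
            trained.predict_scores(np.zeros((2, 32, 32)))

    def test_activation_stack_counts_and_shapes(self, trained):
        image = np.zeros((64, 64))
        for layer, (f, h, w) in enumerate(trained.net.stage_shapes, start=1):
            stack = trained.layer_activations(image, layer)
            assert stack.shape == (f, h, w)

    def test_zero_input_gives_bias_constant_maps(self, trained):
        stack = trained.layer_activations(np.zeros((64, 64)), 1)
        # each filter map is constant (equal to its bias) on a zero image
        assert np.allclose(stack, stack[:, :1, :1])

    def test_invalid_layer_rejected(self, trained):
        with pytest.raises(IndexError):
            trained.layer_activations(np.zeros((64, 64)), 4)
        with pytest.raises(IndexError):
            trained.layer_activations(np.zeros((64, 64)), "addition")

    def test_save_load_roundtrip(self, trained, tmp_path, strong_cohort):
        path = tmp_path / "model.npz"
        trained.save(path)
        back = TrainedModel.load(path)
        assert np.allclose(
            back.predict_scores(strong_cohort), trained.predict_scores(strong_cohort)
        )
        assert back.family == "cnn"

    def test_summary_mentions_architecture(self, trained):
        text = trained.summary()
        assert "conv1" in text and "softmax" in text
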