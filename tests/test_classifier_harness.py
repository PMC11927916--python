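import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from glaupie.classifier_harness import (
    G_VS_S,
    GS_VS_N,
    BinaryTask,
    TrainConfig,
    build_model,
    combine_binary_probabilities,
    count_macs,
    focal_loss,
    predict_three_class,
    profile_model,
    stratified_folds,
    train,
)
from glaupie.nn import ViTConfig, VisionTransformer


class TestBuildModel:
    def test_sigmoid_output_in_unit_interval(self, tiny_train_config):
        model = build_model(tiny_train_config)
        x = np.random.default_rng(0).random((2, 32, 32, 3))
        p = model.predict_proba(x)
        assert np.all((p > 0) & (p < 1))

    def test_deit_small_token_grid_is_14_by_14(self):
        cfg = TrainConfig().vit_config()
        assert cfg.grid_size == 14
        assert cfg.num_patches == 196

    def test_same_seed_same_first_batch_loss(self, tiny_train_config):
        x = np.random.default_rng(1).random((4, 32, 32, 3))
        y = np.array([1, 0, 1, 0])
        losses = []
        for _ in range(2):
            model = build_model(tiny_train_config)
            p = model.predict_proba(x)
            losses.append(focal_loss(p, y, gamma=2.0).mean())
        assert losses[0] == losses[1]

    def test_unknown_backbone_rejected(self):
        with pytest.raises(ValueError, match="backbone"):
            TrainConfig(backbone="resnet50").vit_config()

    def test_task_sides_must_be_disjoint(self):
        with pytest.raises(ValueError):
            BinaryTask("bad", ("G",), ("G", "N"))


class TestFocalLoss:
    @given(p=st.floats(0.01, 0.99), y=st.integers(0, 1))
    def test_gamma_zero_is_binary_cross_entropy(self, p, y):
        bce = -(y * np.log(p) + (1 - y) * np.log(1 - p))
        assert focal_loss(p, y, alpha=1.0, gamma=0.0) == pytest.approx(bce)

    def test_closed_form_at_half(self):
        assert focal_loss(0.5, 1, alpha=1.0, gamma=2.0) == pytest.approx(0.25 * np.log(2))

    def test_monotone_decreasing_in_true_class_probability(self):
        probs = np.linspace(0.05, 0.95, 40)
        losses = focal_loss(probs, np.ones_like(probs), alpha=1.0, gamma=2.0)
        assert np.all(np.diff(losses) < 0)

    def test_probabilities_at_bounds_clamped(self):
        assert np.isfinite(focal_loss(0.0, 1))
        assert np.isfinite(focal_loss(1.0, 0))


class TestStratifiedFolds:
    @staticmethod
    def _manifest(per_class):
        labels = sum(([c] * n for c, n in per_class.items()), [])
        return pd.DataFrame({"label": labels})

    def test_exact_division(self):
        folds = stratified_folds(self._manifest({"G": 10, "S": 10, "N": 10}), 5, 0)
        df = self._manifest({"G": 10, "S": 10, "N": 10}).assign(fold=folds)
        assert (df.groupby(["label", "fold"]).size() == 2).all()

    def test_remainder_spread(self):
        m = self._manifest({"G": 11, "S": 11, "N": 11})
        folds = stratified_folds(m, 5, 0)
        sizes = m.assign(fold=folds).groupby(["label", "fold"]).size()
        assert set(sizes) <= {2, 3}

    def test_folds_partition_the_manifest(self):
        m = self._manifest({"G": 7, "S": 9, "N": 13})
        folds = stratified_folds(m, 3, 1)
        assert np.all(folds >= 0) and len(folds) == len(m)
        assert set(folds) == {0, 1, 2}

    def test_k_larger_than_smallest_class_rejected(self):
        with pytest.raises(ValueError, match="smallest class"):
            stratified_folds(self._manifest({"G": 3, "S": 10, "N": 10}), 5, 0)

    @given(ng=st.integers(5, 20), ns=st.integers(5, 20), nn=st.integers(5, 20))
    def test_per_class_fold_counts_differ_by_at_most_one(self, ng, ns, nn):
        m = self._manifest({"G": ng, "S": ns, "N": nn})
        folds = stratified_folds(m, 5, 0)
        sizes = m.assign(fold=folds).groupby(["label", "fold"]).size().unstack(fill_value=0)
        assert ((sizes.max(axis=1) - sizes.min(axis=1)) <= 1).all()


class TestTrain:
    def test_smoke_one_epoch_logs_finite_loss(self, tiny_manifest, tiny_train_config):
        manifest, images = tiny_manifest
        cfg = TrainConfig(**{**tiny_train_config.__dict__, "epochs": 1})
        model, log = train(GS_VS_N, manifest, cfg, images=images)
        assert len(log) == 1
        assert np.isfinite(log["loss"]).all()

    def test_separable_cohort_reaches_high_training_accuracy(
        self, tiny_manifest, tiny_train_config
    ):
        """Bright vs dark discs are linearly separable; the tiny
        transformer exceeds 90% training accuracy within a few epochs."""
        manifest, images = tiny_manifest
        _, log = train(GS_VS_N, manifest, tiny_train_config, images=images)
        assert log["train_acc"].iloc[-1] > 0.90

    def test_training_is_deterministic(self, tiny_manifest, tiny_train_config):
        manifest, images = tiny_manifest
        cfg = TrainConfig(**{**tiny_train_config.__dict__, "epochs": 2})
        _, log_a = train(GS_VS_N, manifest, cfg, images=images)
        _, log_b = train(GS_VS_N, manifest, cfg, images=images)
        assert log_a["loss"].iloc[-1] == log_b["loss"].iloc[-1]

    def test_missing_side_rejected(self, tiny_train_config):
        manifest = pd.DataFrame({
            "path": ["a"], "label": ["G"], "eye_side": ["OD"],
            "agreement": ["3/3"], "split": ["train"],
        })
        with pytest.raises(ValueError, match="one side"):
            train(GS_VS_N, manifest, tiny_train_config, images=np.zeros((1, 32, 32, 3)))

    def test_missing_image_paths_listed(self, tiny_train_config):
        manifest = pd.DataFrame({
            "path": ["/nonexistent/a.png", "/nonexistent/b.png"],
            "label": ["G", "N"], "eye_side": ["OD"] * 2,
            "agreement": ["3/3"] * 2, "split": ["train"] * 2,
        })
        with pytest.raises(FileNotFoundError, match="nonexistent"):
            train(GS_VS_N, manifest, tiny_train_config)

    def test_distillation_from_teacher_runs(self, tiny_manifest, tiny_train_config):
        manifest, images = tiny_manifest
        teacher = build_model(tiny_train_config)
        cfg = TrainConfig(**{**tiny_train_config.__dict__, "epochs": 1})
        _, log = train(GS_VS_N, manifest, cfg, images=images, teacher=teacher)
        assert np.isfinite(log["loss"]).all()

    def test_cross_validation_logs_every_fold(self, tiny_manifest, tiny_train_config):
        manifest, images = tiny_manifest
        cfg = TrainConfig(**{**tiny_train_config.__dict__, "epochs": 1, "folds": 2})
        _, log = train(GS_VS_N, manifest, cfg, images=images)
        assert set(log["fold"]) == {0, 1}
        assert "val_acc" in log.columns


class TestPredictThreeClass:
    def test_certain_no_glaucoma_boundary(self):
        probs = combine_binary_probabilities(0.0, 0.7)
        assert probs == {"G": 0.0, "S": 0.0, "N": 1.0}

    def test_certain_glaucoma_boundary(self):
        probs = combine_binary_probabilities(1.0, 1.0)
        assert probs == {"G": 1.0, "S": 0.0, "N": 0.0}

    @given(p_gs=st.floats(0, 1), p_g=st.floats(0, 1))
    def test_probabilities_lie_on_the_simplex(self, p_gs, p_g):
        probs = combine_binary_probabilities(p_gs, p_g)
        assert all(0 <= v <= 1 for v in probs.values())
        assert sum(probs.values()) == pytest.approx(1.0)

    def test_model_pair_prediction_sums_to_one(self, tiny_train_config):
        m1 = build_model(tiny_train_config)
        m2 = build_model(TrainConfig(**{**tiny_train_config.__dict__, "seed": 1}))
        img = np.random.default_rng(0).random((32, 32, 3))
        probs = predict_three_class(m1, m2, img)
        assert sum(probs.values()) == pytest.approx(1.0)

    def test_input_size_mismatch_rejected(self, tiny_train_config):
        m = build_model(tiny_train_config)
        with pytest.raises(ValueError, match="input"):
            predict_three_class(m, m, np.zeros((16, 16, 3)))


class TestProfileModel:
    def test_deit_small_parameter_count_rounds_to_22M(self):
        stats = profile_model(TrainConfig())
        assert round(stats["parameters_millions"]) == 22

    def test_toy_transformer_matches_analytic_parameter_count(self):
        cfg = ViTConfig(img_size=32, patch_size=8, embed_dim=64, depth=2, num_heads=2)
        model = VisionTransformer(cfg)
        d, hidden, t = 64, 256, 4 * 4 + 2
        per_block = (2 * d + 2 * d) + (d * 3 * d + 3 * d) + (d * d + d) \
            + (d * hidden + hidden) + (hidden * d + d)
        expected = (8 * 8 * 3 * d + d) + 2 * d + t * d + 2 * per_block \
            + 2 * d + 2 * (d + 1)
        assert model.num_parameters() == expected

    def test_deeper_toy_model_has_strictly_more_parameters(self):
        shallow = VisionTransformer(
            ViTConfig(img_size=32, patch_size=8, embed_dim=64, depth=2, num_heads=2))
        deep = VisionTransformer(
            ViTConfig(img_size=32, patch_size=8, embed_dim=64, depth=4, num_heads=2))
        assert deep.num_parameters() > shallow.num_parameters()

    def test_mac_estimate_reported_in_billions(self):
        stats = profile_model(TrainConfig())
        assert stats["macs_billions"] == pytest.approx(4.6, abs=0.2)
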