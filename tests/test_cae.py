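import numpy as np
import pytest

from evsort.cae import (CAEConfig, CAEWeights, build_cae, count_parameters,
                        extract_features, feature_channel_map, reconstruct,
                        train_cae)
from evsort.simulate import generate_cells


@pytest.fixture(scope="module")
def tiny_trained(small_cohort):
    """A briefly trained CAE on 120 cells (fast, shared across tests)."""
    pixels, _, _ = small_cohort
    cfg = CAEConfig(epochs=4, batch_size=32, seed=3)
    model = build_cae(cfg)
    weights, history = train_cae(model, pixels, cfg)
    return weights, history, pixels


class TestBuild:
    def test_bottleneck_shapes(self):
        model = build_cae()
        x = np.zeros((2, 32, 32, 2), dtype=np.float32)
        z0 = model.enc0.forward(x[..., :1], False)
        assert z0.shape == (2, 4, 4, 8)  # 4x4x8 per channel
        feats = model.encode(x)
        assert feats.shape == (2, 256)

    def test_default_parameter_budget(self):
        assert 170_000 <= count_parameters(build_cae()) <= 230_000

    def test_bad_configs_rejected(self):
        with pytest.raises(ValueError):
            build_cae(CAEConfig(encoder_widths=(16, 32, 4)))  # wrong bottleneck
        with pytest.raises(ValueError):
            build_cae(CAEConfig(encoder_widths=()))
        with pytest.raises(ValueError):
            build_cae(CAEConfig(decoder_widths=(8,)))
        with pytest.raises(ValueError):
            CAEConfig(loss="huber")


class TestTraining:
    def test_seeded_training_is_reproducible(self, small_cohort):
        pixels, _, _ = small_cohort
        cfg = CAEConfig(epochs=3, batch_size=32, seed=11)
        w1, h1 = train_cae(build_cae(cfg), pixels, cfg)
        w2, h2 = train_cae(build_cae(cfg), pixels, cfg)
        assert h1.best_epoch == h2.best_epoch
        assert h1.val_loss == h2.val_loss
        np.testing.assert_array_equal(w1.state["dec.0.w"], w2.state["dec.0.w"])

    def test_best_epoch_is_argmin_of_validation_loss(self, tiny_trained):
        _, history, _ = tiny_trained
        assert history.best_epoch == int(np.argmin(history.val_loss))
        assert history.val_loss[history.best_epoch] <= history.val_loss[0]

    def test_training_beats_untrained_reconstruction(self, tiny_trained):
        weights, _, pixels = tiny_trained
        probe = pixels[:32].astype(np.float64)

        def mse(model_or_weights):
            return float(np.mean((reconstruct(model_or_weights,
                                              pixels[:32]) - probe) ** 2))

        assert mse(weights) < mse(build_cae(CAEConfig(seed=99)))

    def test_too_small_dataset_rejected(self):
        pixels, _, _ = generate_cells(5, 5, seed=0)
        cfg = CAEConfig(epochs=1, batch_size=64)
        with pytest.raises(ValueError, match="batch"):
            train_cae(build_cae(cfg), pixels, cfg)

    def test_mae_loss_gives_equivalent_downstream_auc(self, small_cohort):
        """Training with MAE instead of MSE yields sorting AUC within 0.05
        of the MSE-trained features on the synthetic benchmark."""
        from evsort.evaluate import roc_auc
        from evsort.sorter import RFConfig, train_rf

        pixels, labels, _ = small_cohort
        test_px, test_lab, _ = generate_cells(40, 40, seed=999)
        aucs = {}
        for loss in ("mse", "mae"):
            cfg = CAEConfig(epochs=4, batch_size=32, loss=loss, seed=5)
            weights, history = train_cae(build_cae(cfg), pixels, cfg)
            assert np.all(np.isfinite(history.val_loss))
            forest = train_rf(extract_features(weights, pixels), labels,
                              RFConfig(n_trees=200, seed=6))
            p = forest.predict_proba(extract_features(weights, test_px))
            p_ev = p[:, list(forest.classes_).index("ev")]
            aucs[loss] = roc_auc(p_ev, test_lab).auc
        assert abs(aucs["mse"] - aucs["mae"]) <= 0.05


class TestFeatures:
    def test_vector_length_256_and_finite(self, tiny_trained):
        weights, _, pixels = tiny_trained
        feats = extract_features(weights, pixels[:10])
        assert feats.shape == (10, 256)
        assert np.all(np.isfinite(feats))

    def test_extraction_is_deterministic(self, tiny_trained):
        weights, _, pixels = tiny_trained
        f1 = extract_features(weights, pixels[:5])
        f2 = extract_features(weights, pixels[:5])
        np.testing.assert_array_equal(f1, f2)

    def test_channel_encoders_are_independent(self, tiny_trained):
        """Zeroing the fluorescence channel may only change coordinates
        128..255; the brightfield half belongs to the other encoder."""
        weights, _, pixels = tiny_trained
        probe = pixels[:4].copy()
        base = extract_features(weights, probe)
        probe[:, 1] = 0
        blanked = extract_features(weights, probe)
        np.testing.assert_array_equal(base[:, :128], blanked[:, :128])
        assert np.any(base[:, 128:] != blanked[:, 128:])

    def test_features_distinguish_blank_from_bright(self, tiny_trained):
        weights, _, pixels = tiny_trained
        blank = np.zeros((1, 2, 32, 32), dtype=np.uint16)
        bright = pixels[:1]
        fa = extract_features(weights, blank)
        fb = extract_features(weights, bright)
        assert np.linalg.norm(fa - fb) > 0

    def test_channel_map_halves(self):
        cmap = feature_channel_map()
        assert list(cmap[:128]) == ["brightfield"] * 128
        assert list(cmap[128:]) == ["fluorescence"] * 128


class TestReconstruct:
    def test_output_shape_matches_input(self, tiny_trained):
        weights, _, pixels = tiny_trained
        out = reconstruct(weights, pixels[0])
        assert out.shape == (2, 32, 32)

    def test_untrained_model_output_is_finite(self, small_cohort):
        pixels, _, _ = small_cohort
        out = reconstruct(build_cae(), pixels[0])
        assert np.all(np.isfinite(out))


class TestWeightsSerialisation:
    def test_save_load_identity(self, tiny_trained, tmp_path):
        weights, _, pixels = tiny_trained
        path = tmp_path / "cae.npz"
        weights.save(path)
        back = CAEWeights.load(path)
        assert set(back.state) == set(weights.state)
        for k in weights.state:
            np.testing.assert_array_equal(back.state[k], weights.state[k])
        np.testing.assert_array_equal(
            extract_features(back, pixels[:3]),
            extract_features(weights, pixels[:3]))
        assert back.config_hash == weights.config_hash
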