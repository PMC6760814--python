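"""Model structure (antisymmetry, permutation invariance, weights) and training."""

import numpy as np
import pytest

from fishrules import networks as nw
from fishrules.features import DataBundle, Standardizer, reflect

from conftest import make_toy_samples


def fitted_standardizer(samples):
    return Standardizer(
        samples.alpha_names, samples.social_names, samples.weight_names
    ).fit(samples.alpha, samples.social, samples.wfeat)


def toy_bundle(rule="nearest_x", n=512, n_neighbours=5, seed=0):
    train = make_toy_samples(n, n_neighbours, seed=seed, rule=rule)
    val = make_toy_samples(max(n // 4, 64), n_neighbours, seed=seed + 1, rule=rule)
    test = make_toy_samples(max(n // 4, 64), n_neighbours, seed=seed + 2, rule=rule)
    return DataBundle(
        train=train, validation=val, test=test,
        standardizer=fitted_standardizer(train),
    )


@pytest.fixture(params=["attention", "interaction", "focal_only"])
def untrained_model(request, toy_samples):
    std = fitted_standardizer(toy_samples)
    return nw.make_network(request.param, std, seed=11)


class TestStructure:
    def test_antisymmetric_under_body_axis_reflection(self, untrained_model, toy_samples):
        z = untrained_model.predict_logits(toy_samples)
        z_ref = untrained_model.predict_logits(reflect(toy_samples))
        np.testing.assert_allclose(z_ref, -z, rtol=1e-5, atol=1e-6)

    def test_permutation_invariance_over_neighbours(self, untrained_model, toy_samples):
        rng = np.random.default_rng(2)
        perm = rng.permutation(toy_samples.n_neighbours)
        shuffled = toy_samples.subset(slice(None))
        shuffled.social = shuffled.social[:, perm]
        shuffled.wfeat = shuffled.wfeat[:, perm]
        z1 = untrained_model.predict_logits(toy_samples)
        z2 = untrained_model.predict_logits(shuffled)
        np.testing.assert_allclose(z1, z2, rtol=1e-4, atol=1e-5)

    def test_attention_weights_positive_and_normalized(self, toy_samples):
        std = fitted_standardizer(toy_samples)
        model = nw.make_network("attention", std, seed=5)
        _, weights, _ = model.attention_logit(toy_samples)
        assert (weights > 0).all()
        omega = model.neighbour_weights(toy_samples)
        np.testing.assert_allclose(omega.sum(axis=1), 1.0, rtol=1e-5)
        assert (omega > 0).all()

    def test_attention_logit_is_weighted_average_of_pair_logits(self, toy_samples):
        std = fitted_standardizer(toy_samples)
        model = nw.make_network("attention", std, seed=5)
        z, weights, pi = model.attention_logit(toy_samples)
        omega = weights / weights.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(z, (omega * pi).sum(axis=1), rtol=1e-4, atol=1e-6)
        # the logit therefore lies between the extreme pair contributions
        assert (z <= pi.max(axis=1) + 1e-6).all()
        assert (z >= pi.min(axis=1) - 1e-6).all()

    def test_manifest_mismatch_refused(self, toy_samples):
        std = fitted_standardizer(toy_samples)
        model = nw.make_network("attention", std, seed=0)
        other = make_toy_samples(16, 5, seed=9)
        other.social_names = ("x", "y", "vx", "vy", "topo")
        with pytest.raises(ValueError, match="manifest"):
            model.predict_logits(other)


class TestLossAndProbability:
    def test_logistic_map_examples(self):
        assert nw.logit_to_probability(0.0) == pytest.approx(0.5)
        assert nw.logit_to_probability(50.0) == pytest.approx(1.0)
        z = np.linspace(-4, 4, 11)
        np.testing.assert_allclose(
            nw.logit_to_probability(-z), 1 - nw.logit_to_probability(z), atol=1e-12
        )

    def test_cross_entropy_hand_computed_batch(self):
        p = np.array([0.9, 0.2, 0.5])
        y = np.array([1, 0, 1])
        expected = -(np.log(0.9) + np.log(0.8) + np.log(0.5)) / 3
        assert nw.cross_entropy_loss(p, y) == pytest.approx(expected)

    def test_uninformative_predictions_give_log2(self):
        assert nw.cross_entropy_loss(
            np.full(10, 0.5), np.arange(10) % 2
        ) == pytest.approx(np.log(2))

    def test_confident_correct_predictions_vanishing_loss(self):
        assert nw.cross_entropy_loss(np.array([1.0, 0.0]), np.array([1, 0])) < 1e-9

    def test_probabilities_clamped_before_log(self):
        assert np.isfinite(nw.cross_entropy_loss(np.array([0.0]), np.array([1])))


class TestTrainConfig:
    def test_schedule_monotone_decreasing(self):
        cfg = nw.TrainConfig(model_kind="attention", max_epochs=20)
        lrs = [cfg.learning_rate(e) for e in range(20)]
        assert lrs[0] == pytest.approx(1e-4) and lrs[-1] == pytest.approx(1e-5)
        assert all(a > b for a, b in zip(lrs, lrs[1:]))

    def test_kind_defaults(self):
        assert nw.TrainConfig(model_kind="attention").batch_size == 500
        cfg = nw.TrainConfig(model_kind="interaction")
        assert cfg.batch_size == 200 and cfg.lr_start == pytest.approx(5e-5)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            nw.TrainConfig(model_kind="perceptron")
        with pytest.raises(ValueError):
            nw.TrainConfig(model_kind="attention", lr_start=1e-6, lr_end=1e-4)


class TestTraining:
    @pytest.mark.parametrize(
        "kind,lr,epochs", [("attention", 2e-3, 15), ("interaction", 5e-3, 30)]
    )
    def test_separable_rule_learned(self, kind, lr, epochs):
        """Label = side of the nearest neighbour: noiseless, so accuracy > 95%."""
        bundle = toy_bundle("nearest_x", n=3000)
        cfg = nw.TrainConfig(
            model_kind=kind, max_epochs=epochs, lr_start=lr, lr_end=lr / 4, seed=0
        )
        model = nw.make_network(kind, bundle.standardizer, seed=1)
        nw.train(model, bundle, cfg)
        assert nw.evaluate_accuracy(model, bundle.test) > 0.95

    def test_random_labels_stay_at_chance_and_early_stop(self):
        bundle = toy_bundle("random", n=400)
        cfg = nw.TrainConfig(
            model_kind="attention", max_epochs=80, lr_start=3e-3, lr_end=3e-3,
            seed=0, patience=10,
        )
        model = nw.make_network("attention", bundle.standardizer, seed=1)
        history = nw.train(model, bundle, cfg)
        assert history["n_epochs"] < 80  # overfitting triggers the stop rule
        assert 0.35 <= nw.evaluate_accuracy(model, bundle.test) <= 0.65

    def test_training_is_deterministic_given_seed(self):
        bundle = toy_bundle("nearest_x", n=400)
        histories = []
        for _ in range(2):
            cfg = nw.TrainConfig(model_kind="attention", max_epochs=3, seed=42)
            model = nw.make_network("attention", bundle.standardizer, seed=7)
            histories.append(nw.train(model, bundle, cfg))
        assert histories[0]["train_loss"] == histories[1]["train_loss"]
        assert histories[0]["val_loss"] == histories[1]["val_loss"]

    def test_best_epoch_parameters_restored(self):
        bundle = toy_bundle("random", n=300)
        cfg = nw.TrainConfig(
            model_kind="attention", max_epochs=40, lr_start=3e-3, lr_end=3e-3, seed=3
        )
        model = nw.make_network("attention", bundle.standardizer, seed=4)
        history = nw.train(model, bundle, cfg)
        z = model.predict_logits(bundle.validation)
        val_loss = float(np.mean(
            np.logaddexp(0, z) - bundle.validation.label * z
        ))
        assert val_loss == pytest.approx(history["best_val_loss"], rel=1e-5)


class TestEvaluation:
    def test_perfect_toy_set(self, toy_samples):
        std = fitted_standardizer(toy_samples)
        model = nw.make_network("attention", std, seed=0)
        z = model.predict_logits(toy_samples)
        rigged = toy_samples.subset(slice(None))
        rigged.label = (z >= 0).astype(np.int8)
        assert nw.evaluate_accuracy(model, rigged) == 1.0

    def test_empty_angle_range_rejected(self, toy_samples):
        std = fitted_standardizer(toy_samples)
        model = nw.make_network("attention", std, seed=0)
        rigged = toy_samples.subset(slice(None))
        rigged.turn_angle = np.full(len(rigged), 50.0)
        with pytest.raises(ValueError, match="turn angle"):
            nw.evaluate_accuracy(model, rigged, (100, 140))

    def test_accuracy_decomposes_over_angle_partition(self, toy_samples):
        std = fitted_standardizer(toy_samples)
        model = nw.make_network("attention", std, seed=0)
        edges = [(0, 60), (60.0000001, 120), (120.0000001, 180)]
        total = nw.evaluate_accuracy(model, toy_samples, (0, 180))
        weighted = 0.0
        for lo, hi in edges:
            keep = (toy_samples.turn_angle >= lo) & (toy_samples.turn_angle <= hi)
            weighted += keep.mean() * nw.evaluate_accuracy(model, toy_samples, (lo, hi))
        assert weighted == pytest.approx(total)


class TestCheckpoints:
    def test_roundtrip_preserves_predictions(self, tmp_path, toy_samples):
        std = fitted_standardizer(toy_samples)
        model = nw.make_network("attention", std, seed=3)
        path = nw.save_checkpoint(model, nw.TrainConfig(), tmp_path / "m.npz")
        back, manifest = nw.load_checkpoint(path)
        assert manifest["kind"] == "attention"
        np.testing.assert_allclose(
            back.predict_logits(toy_samples), model.predict_logits(toy_samples)
        )

    def test_loaded_model_refuses_mismatched_data(self, tmp_path, toy_samples):
        std = fitted_standardizer(toy_samples)
        model = nw.make_network("attention", std, seed=3)
        path = nw.save_checkpoint(model, None, tmp_path / "m.npz")
        back, _ = nw.load_checkpoint(path)
        other = make_toy_samples(8, 5, seed=1)
        other.alpha_names = ("v", "a_perp", "a_par")
        with pytest.raises(ValueError, match="manifest"):
            back.predict_logits(other)
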