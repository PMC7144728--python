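"""Image-classifier backend, checkpoint selection, descriptors, baselines."""

import numpy as np
import pandas as pd
import pytest

from molsnap.chemio import MoleculeRecord
from molsnap.modeling import (EpochTrace, SmallImageNet, TrainSpec,
                              compute_descriptors, make_prediction_table,
                              predict_images, train_baseline,
                              train_image_classifier, SOLVERS)
from molsnap.snapshot import Orientation


def _toy_images(n=120, size=32, seed=0):
    """Black vs white squares with pixel noise: separable by intensity."""
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, n)
    imgs = np.where(y[:, None, None, None] == 1, 200, 20).astype(np.uint8)
    imgs = np.broadcast_to(imgs, (n, size, size, 3)).copy()
    imgs += rng.integers(0, 20, imgs.shape).astype(np.uint8)
    return imgs, y


class TestTrainSpec:
    def test_defaults_are_the_tuned_operating_point(self):
        spec = TrainSpec()
        assert (spec.solver, spec.learning_rate, spec.batch_size,
                spec.epochs) == ("NAG", 0.0025, 37, 30)

    @pytest.mark.parametrize("kw", [dict(solver="FancyGrad"),
                                    dict(learning_rate=0.0),
                                    dict(batch_size=0), dict(epochs=0)])
    def test_invalid_spec_rejected(self, kw):
        with pytest.raises(ValueError):
            TrainSpec(**kw)


class TestEpochTrace:
    def test_best_epoch_is_argmin_of_val_loss(self):
        trace = EpochTrace((0.9, 0.3, 0.5), (50.0, 80.0, 70.0))
        assert trace.best_epoch == 1

    def test_bounds_validated(self):
        with pytest.raises(ValueError):
            EpochTrace((0.5, -0.1), (50.0, 50.0))
        with pytest.raises(ValueError):
            EpochTrace((0.5,), (120.0,))


class TestSmallImageNet:
    def test_separable_toy_reaches_full_val_accuracy(self):
        imgs, y = _toy_images()
        model, trace = train_image_classifier(
            imgs[:90], y[:90], imgs[90:], y[90:],
            TrainSpec(epochs=5, seed=0), model=SmallImageNet(n_models=1))
        assert trace.val_acc[trace.best_epoch] == 100.0

    def test_restored_checkpoint_has_min_val_loss(self):
        imgs, y = _toy_images(seed=3)
        net = SmallImageNet(n_models=1)
        trace = net.fit(imgs[:90], y[:90], imgs[90:], y[90:],
                        TrainSpec(epochs=6, seed=1))
        xv = (net._featurize(imgs[90:]) - net.feature_mean) / net.feature_std
        _, pv = net._forward(net.params, xv)
        restored = net._loss(pv, y[90:])
        assert restored == pytest.approx(min(trace.val_loss))

    @pytest.mark.parametrize("solver", SOLVERS)
    def test_every_solver_learns_the_toy_problem(self, solver):
        imgs, y = _toy_images(seed=4)
        lr = 0.01 if solver in ("NAG", "SGD") else 0.05
        net = SmallImageNet(hidden=16, n_models=1)
        trace = net.fit(imgs[:90], y[:90], imgs[90:], y[90:],
                        TrainSpec(solver=solver, learning_rate=lr,
                                  epochs=8, seed=0))
        assert min(trace.val_loss) < 0.5
        assert trace.val_acc[trace.best_epoch] > 80.0

    def test_single_class_training_rejected(self):
        imgs, _ = _toy_images(24)
        with pytest.raises(ValueError, match="both classes"):
            SmallImageNet(n_models=1).fit(
                imgs[:12], np.ones(12, int), imgs[12:], np.ones(12, int),
                TrainSpec(epochs=1))

    def test_same_seed_same_predictions(self):
        imgs, y = _toy_images(seed=6)
        probs = []
        for _ in range(2):
            net = SmallImageNet(n_models=2)
            net.fit(imgs[:90], y[:90], imgs[90:], y[90:],
                    TrainSpec(epochs=3, seed=5))
            probs.append(net.predict_proba(imgs[90:]))
        np.testing.assert_array_equal(probs[0], probs[1])


@pytest.fixture(scope="module")
def trained():
    imgs, y = _toy_images(seed=8)
    model, _ = train_image_classifier(imgs[:90], y[:90], imgs[90:], y[90:],
                                      TrainSpec(epochs=3, seed=2))
    return model, imgs


class TestPredictImages:
    def test_pure_function_on_duplicates(self, trained):
        model, imgs = trained
        doubled = np.concatenate([imgs[:5], imgs[:5]])
        p = predict_images(model, doubled)
        # equal up to one ulp: BLAS blocking may round rows differently
        np.testing.assert_allclose(p[:5], p[5:], rtol=0, atol=1e-12)

    def test_probabilities_in_unit_interval_on_noise(self, trained):
        model, _ = trained
        noise = np.random.default_rng(0).integers(0, 255, (10, 32, 32, 3),
                                                  dtype=np.uint8)
        p = predict_images(model, noise)
        assert p.min() >= 0.0 and p.max() <= 1.0

    def test_batch_equals_single_image_inference(self, trained):
        model, imgs = trained
        batch = predict_images(model, imgs[:8])
        singles = np.concatenate([predict_images(model, imgs[i:i + 1])
                                  for i in range(8)])
        np.testing.assert_allclose(batch, singles, rtol=1e-12)

    def test_resolution_mismatch_rejected(self, trained):
        model, _ = trained
        with pytest.raises(ValueError, match="resolution"):
            predict_images(model, np.zeros((2, 64, 64, 3), dtype=np.uint8))


class TestPredictionTable:
    def test_duplicate_orientation_rows_rejected(self):
        o = Orientation(0, 0, 0)
        with pytest.raises(ValueError, match="duplicate"):
            make_prediction_table(["a", "a"], [o, o], [0.5, 0.6])


class TestDescriptors:
    def test_ethane_vs_ethanol_differ_in_oxygen_count(self):
        table = compute_descriptors([MoleculeRecord("ethane", "CC", 1.0),
                                     MoleculeRecord("ethanol", "CCO", 1.0)])
        assert table.loc["ethane", "NumHAcceptors"] == 0
        assert table.loc["ethanol", "NumHAcceptors"] == 1

    def test_benzene_heavy_atom_count(self):
        table = compute_descriptors([MoleculeRecord("benzene", "c1ccccc1", 1.0)])
        assert table.loc["benzene", "HeavyAtomCount"] == 6

    def test_deterministic_and_finite(self, ten_records):
        a = compute_descriptors(ten_records)
        b = compute_descriptors(ten_records)
        pd.testing.assert_frame_equal(a, b)
        assert np.isfinite(a.to_numpy()).all()


@pytest.fixture(scope="module")
def separable():
    rng = np.random.default_rng(0)
    y = rng.integers(0, 2, 60)
    x = pd.DataFrame({"d1": y + 0.01 * rng.random(60),
                      "d2": rng.random(60)},
                     index=[f"m{i}" for i in range(60)])
    return x, y


class TestBaselines:
    @pytest.mark.parametrize("learner", ["RF", "XGB", "LGBM"])
    def test_separable_training_auc_is_one(self, separable, learner):
        from sklearn.metrics import roc_auc_score
        x, y = separable
        model = train_baseline(x, y, learner, seed=0)
        assert roc_auc_score(y, model.predict_proba(x.to_numpy())[:, 1]) == 1.0

    def test_same_seed_identical_predictions(self, separable):
        x, y = separable
        p = [train_baseline(x, y, "RF", seed=3).predict_proba(x.to_numpy())
             for _ in range(2)]
        np.testing.assert_array_equal(p[0], p[1])

    def test_missing_catboost_backend_names_the_arm(self, separable):
        x, y = separable
        try:
            import catboost  # noqa: F401
        except ImportError:
            with pytest.raises(ImportError, match="CB"):
                train_baseline(x, y, "CB", seed=0)
        else:
            pytest.skip("catboost installed; missing-backend path not reachable")

    def test_unknown_learner_rejected(self, separable):
        x, y = separable
        with pytest.raises(ValueError, match="unknown learner"):
            train_baseline(x, y, "SVM", seed=0)
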