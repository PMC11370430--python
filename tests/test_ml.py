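"""Classifier stack: tensor assembly, layer gradients, training
behavior on controlled data, and evaluation metrics."""

import numpy as np
import pytest

from ctcflow.dataset import TrajectoryDataset
from ctcflow.ml import (ModelSpec, assemble_training_arrays,
                        auc_trapezoid, evaluate_classifier, make_classifier,
                        resample_sequence, roc_curve_points, train_classifier)
from ctcflow.ml.layers import (Adam, BatchNorm, BiRNN, Conv1D, Dense,
                               Dropout, Sequential, cross_entropy)


def _synthetic_dataset(n=120, T=40, offset=1.0, seed=0):
    """Two classes separated by a constant lateral offset plus noise."""
    rng = np.random.default_rng(seed)
    seqs, labels, times = [], [], []
    for k in range(n):
        lab = k % 2
        seq = 0.5 * rng.standard_normal((T, 6))
        seq[:, 1] += offset * (2 * lab - 1)
        seqs.append(seq)
        labels.append("stiff" if lab else "soft")
        times.append(np.arange(T) * 1e-3)
    return TrajectoryDataset(seqs, labels, times, meta={"seed": seed})


class TestResampling:
    def test_linear_sequences_resampled_exactly(self):
        t = np.linspace(0, 1, 17)
        seq = np.column_stack([2 * t, -t + 3])
        out = resample_sequence(seq, 33)
        tt = np.linspace(0, 1, 33)
        assert np.allclose(out[:, 0], 2 * tt, atol=1e-12)
        assert np.allclose(out[:, 1], -tt + 3, atol=1e-12)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            resample_sequence(np.zeros((1, 6)), 16)


class TestAssembly:
    def test_split_counting(self):
        ds = _synthetic_dataset(n=40)
        splits = assemble_training_arrays(ds, split=(0.7, 0.15, 0.15),
                                          seed=0, T=32)
        assert len(splits.train.X) == 28
        assert len(splits.val.X) == 6
        assert len(splits.test.X) == 6
        for part in (splits.train, splits.val, splits.test):
            assert set(part.y) == {0, 1}  # both classes everywhere

    def test_same_seed_same_membership(self):
        ds = _synthetic_dataset(n=40)
        a = assemble_training_arrays(ds, seed=3, T=32)
        b = assemble_training_arrays(ds, seed=3, T=32)
        assert np.array_equal(a.train.indices, b.train.indices)
        assert np.array_equal(a.test.indices, b.test.indices)

    def test_train_standardization(self):
        ds = _synthetic_dataset(n=60)
        splits = assemble_training_arrays(ds, seed=0, T=32)
        assert np.allclose(splits.train.X.mean(axis=(0, 2)), 0.0, atol=1e-10)
        assert np.allclose(splits.train.X.std(axis=(0, 2)), 1.0, atol=1e-10)

    def test_single_class_rejected(self):
        ds = _synthetic_dataset(n=20)
        ds.labels = ["soft"] * 20
        with pytest.raises(ValueError):
            assemble_training_arrays(ds, seed=0, T=16)


class TestLayerGradients:
    """Finite-difference checks of the hand-coded backpropagation."""

    def _loss_and_grads(self, net, x, y):
        logits = net.forward(x, train=False)
        loss, dlogits = cross_entropy(logits, y)
        net.backward(dlogits)
        return loss

    @pytest.mark.parametrize("make_net", [
        lambda rng: Sequential(Conv1D(2, 3, 3, rng),
                               __import__("ctcflow.ml.layers",
                                          fromlist=["Flatten"]).Flatten(),
                               Dense(3 * 10, 2, rng)),
        lambda rng: Sequential(BiRNN(2, 4, rng, stride=2),
                               __import__("ctcflow.ml.layers",
                                          fromlist=["LastTimestep"]).LastTimestep(),
                               Dense(8, 2, rng)),
        lambda rng: Sequential(BatchNorm(2),
                               __import__("ctcflow.ml.layers",
                                          fromlist=["Flatten"]).Flatten(),
                               Dense(2 * 12, 2, rng)),
    ], ids=["conv", "birnn", "batchnorm"])
    def test_weight_gradients_match_finite_differences(self, make_net):
        rng = np.random.default_rng(0)
        net = make_net(rng)
        x = rng.standard_normal((5, 2, 12))
        y = np.array([0, 1, 0, 1, 1])
        self._loss_and_grads(net, x, y)
        pairs = list(net.parameters())
        eps = 1e-6
        for p, g in pairs[:3]:
            flat = p.ravel()
            gflat = g.ravel()
            for idx in (0, flat.size // 2, flat.size - 1):
                orig = flat[idx]
                flat[idx] = orig + eps
                lp = cross_entropy(net.forward(x), y)[0]
                flat[idx] = orig - eps
                lm = cross_entropy(net.forward(x), y)[0]
                flat[idx] = orig
                num = (lp - lm) / (2 * eps)
                assert np.isclose(gflat[idx], num, rtol=1e-4, atol=1e-8)

    def test_batchnorm_input_gradient(self):
        rng = np.random.default_rng(1)
        bn = BatchNorm(3)
        x = rng.standard_normal((4, 3, 6))
        y = np.array([0, 1, 1, 0])
        from ctcflow.ml.layers import Flatten
        net = Sequential(bn, Flatten(), Dense(18, 2, rng))
        logits = net.forward(x, train=True)
        loss, dl = cross_entropy(logits, y)
        dx = net.backward(dl)
        eps = 1e-6
        for (i, c, t) in [(0, 0, 0), (2, 1, 3), (3, 2, 5)]:
            xp = x.copy(); xp[i, c, t] += eps
            xm = x.copy(); xm[i, c, t] -= eps
            # batch statistics change with the input: recompute in train mode
            lp = cross_entropy(Sequential(bn, Flatten(),
                                          net.layers[2]).forward(xp, train=True), y)[0]
            lm = cross_entropy(Sequential(bn, Flatten(),
                                          net.layers[2]).forward(xm, train=True), y)[0]
            num = (lp - lm) / (2 * eps)
            assert np.isclose(dx[i, c, t], num, rtol=1e-3, atol=1e-8)


class TestTraining:
    def _splits(self, **kw):
        ds = _synthetic_dataset(**kw)
        return assemble_training_arrays(ds, split=(0.6, 0.2, 0.2),
                                        seed=0, T=32)

    @pytest.mark.parametrize("kind,epochs", [("cnn", 10), ("rnn", 10),
                                             ("baseline", 0)])
    def test_separable_classes_solved(self, kind, epochs):
        splits = self._splits(n=160, offset=1.0)
        spec = ModelSpec(kind=kind, epochs=epochs or 50, seed=1)
        model, _ = train_classifier(splits, spec)
        rep = evaluate_classifier(model, splits.test.X, splits.test.y)
        assert rep.accuracy >= 0.98

    def test_label_shuffle_is_chance_level(self):
        splits = self._splits(n=160, offset=1.0)
        rng = np.random.default_rng(5)
        y_shuffled = rng.permutation(splits.train.y)
        spec = ModelSpec(kind="cnn", epochs=8, seed=2)
        model = make_classifier(spec)
        model.fit(splits.train.X, y_shuffled, splits.val.X,
                  rng.permutation(splits.val.y))
        # permutation control: scored against shuffled labels; 32 test
        # samples give a 3-sigma binomial band around 0.5
        acc = model.score(splits.test.X, rng.permutation(splits.test.y))
        assert abs(acc - 0.5) < 3 * np.sqrt(0.25 / len(splits.test.y)) + 1e-9

    def test_training_is_deterministic(self):
        splits = self._splits(n=80)
        spec = ModelSpec(kind="cnn", epochs=3, seed=7)
        m1, _ = train_classifier(splits, spec)
        m2, _ = train_classifier(splits, ModelSpec(kind="cnn", epochs=3,
                                                   seed=7))
        assert m1.weights_hash() == m2.weights_hash()

    def test_cnn_and_rnn_comparable_on_benchmark(self):
        splits = self._splits(n=200, offset=0.35, seed=4)
        accs = {}
        for kind in ("cnn", "rnn"):
            model, _ = train_classifier(splits, ModelSpec(kind=kind,
                                                          epochs=12, seed=1))
            accs[kind] = evaluate_classifier(model, splits.test.X,
                                             splits.test.y).accuracy
        assert abs(accs["cnn"] - accs["rnn"]) < 0.1

    def test_weight_save_load_round_trip(self, tmp_path):
        splits = self._splits(n=80)
        model, _ = train_classifier(splits, ModelSpec(kind="cnn", epochs=2,
                                                      seed=0))
        path = tmp_path / "w.npz"
        model.save_weights(path)
        clone = make_classifier(ModelSpec(kind="cnn", seed=0))
        clone.load_weights(path)
        assert clone.weights_hash() == model.weights_hash()
        assert np.array_equal(clone.predict(splits.test.X),
                              model.predict(splits.test.X))

    def test_invalid_dropout_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(kind="cnn", dropout=1.2)


class TestEvaluation:
    def test_perfect_scores(self):
        y = np.array([0, 1, 0, 1, 1, 0])
        fpr, tpr, _ = roc_curve_points(y.astype(float), y)
        assert np.isclose(auc_trapezoid(fpr, tpr), 1.0)

    def test_random_scores_near_half(self, rng):
        y = rng.integers(0, 2, size=4000)
        scores = rng.random(4000)
        fpr, tpr, _ = roc_curve_points(scores, y)
        assert abs(auc_trapezoid(fpr, tpr) - 0.5) < 0.03

    def test_auc_equals_rank_statistic_oracle(self, rng):
        """Trapezoid AUC must equal the Mann-Whitney U statistic (and the
        sklearn reference) on identical scores."""
        y = rng.integers(0, 2, size=300)
        scores = rng.standard_normal(300) + 0.4 * y
        fpr, tpr, _ = roc_curve_points(scores, y)
        auc = auc_trapezoid(fpr, tpr)
        pos, neg = scores[y == 1], scores[y == 0]
        # rank-based oracle: P(score_pos > score_neg) + 0.5 P(tie)
        wins = (pos[:, None] > neg[None]).sum()
        ties = (pos[:, None] == neg[None]).sum()
        u_auc = (wins + 0.5 * ties) / (len(pos) * len(neg))
        assert np.isclose(auc, u_auc, atol=1e-12)
        from sklearn.metrics import roc_auc_score
        assert np.isclose(auc, roc_auc_score(y, scores), atol=1e-12)

    def test_roc_monotone(self, rng):
        y = rng.integers(0, 2, size=200)
        scores = rng.random(200)
        fpr, tpr, _ = roc_curve_points(scores, y)
        assert np.all(np.diff(fpr) >= 0)
        assert np.all(np.diff(tpr) >= 0)

    def test_empty_test_split_rejected(self):
        model = make_classifier(ModelSpec(kind="baseline"))
        with pytest.raises(ValueError):
            evaluate_classifier(model, np.empty((0, 6, 8)), np.empty(0, int))
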