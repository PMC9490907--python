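"""Attention pooling, training, evaluation and fold aggregation."""

import numpy as np
import pytest
import scipy.stats

from lfbmil.config import MILConfig
from lfbmil.mil import (
    AttentionMILModel,
    FoldEval,
    aggregate_folds,
    attention_pool,
    auc_score,
    balanced_accuracy,
    evaluate,
    make_splits,
    predict_slide,
    train,
    wilcoxon_vs_null,
    _forward,
    _loss_and_grads,
)
from lfbmil.tiling import FeatureBag


def make_bag(features: np.ndarray, donor_id: str = "d") -> FeatureBag:
    k = len(features)
    coords = np.column_stack([np.arange(k), np.zeros(k, int),
                              np.zeros(k, int), np.arange(k) * 256])
    return FeatureBag(donor_id=donor_id, features=features, coords=coords)


def fresh_model(dim=16, seed=0, **cfg_kw) -> AttentionMILModel:
    return AttentionMILModel.init(dim, MILConfig(embed_dim=8, attn_dim=6, **cfg_kw), seed=seed)


class TestAttentionPool:
    def test_singleton_bag(self, rng):
        model = fresh_model()
        bag = make_bag(rng.normal(size=(1, 16)))
        a, z = attention_pool(bag, model)
        assert a == pytest.approx([1.0])

    def test_identical_tiles_equal_attention(self, rng):
        model = fresh_model()
        tile = rng.normal(size=16)
        bag = make_bag(np.tile(tile, (4, 1)))
        a, _ = attention_pool(bag, model)
        assert a == pytest.approx([0.25] * 4)

    def test_softmax_arithmetic(self):
        # logits [ln 2, 0, 0] -> weights [0.5, 0.25, 0.25]
        e = np.array([np.log(2.0), 0.0, 0.0])
        exp = np.exp(e - e.max())
        assert exp / exp.sum() == pytest.approx([0.5, 0.25, 0.25])

    def test_attention_sums_to_one(self, rng):
        model = fresh_model()
        for k in (2, 7, 33):
            a, z = attention_pool(make_bag(rng.normal(size=(k, 16))), model)
            assert a.sum() == pytest.approx(1.0)
            assert np.all(a > 0)

    def test_nan_features_rejected(self, rng):
        model = fresh_model()
        feats = rng.normal(size=(3, 16))
        feats[1, 2] = np.nan
        with pytest.raises(ValueError):
            _forward(model, feats)


class TestPredict:
    def test_zero_classifier_gives_half(self, rng):
        model = fresh_model()
        model.trained = True  # weights W_c/b_c start at zero
        p = predict_slide(make_bag(rng.normal(size=(5, 16))), model)
        assert p == pytest.approx(0.5)

    def test_untrained_model_rejected(self, rng):
        with pytest.raises(ValueError):
            predict_slide(make_bag(rng.normal(size=(2, 16))), fresh_model())


class TestGradients:
    def test_backprop_matches_numerical_gradient(self, rng):
        """Exact analytic gradients vs central finite differences."""
        model = fresh_model(seed=3, dropout=0.0, instance_loss_weight=0.3, instance_k=2)
        # give the classifier nonzero weights so all paths are exercised
        model.params["W_c"] = rng.normal(0, 0.3, size=model.params["W_c"].shape)
        model.params["W_i"] = rng.normal(0, 0.3, size=model.params["W_i"].shape)
        feats = rng.normal(size=(6, 16))
        g = np.random.default_rng(0)
        _, grads = _loss_and_grads(model, feats, 1, g, training=False)
        eps = 1e-6
        for name in ("W_p", "V", "U", "w", "W_c", "b_c", "W_i", "b_i", "b_p"):
            arr = model.params[name]
            flat_idx = np.unravel_index(
                rng.integers(arr.size, size=min(4, arr.size)), arr.shape)
            for idx in zip(*[np.atleast_1d(a) for a in flat_idx]):
                idx = idx if arr.ndim > 1 else idx[0]
                orig = arr[idx]
                arr[idx] = orig + eps
                lp, _ = _loss_and_grads(model, feats, 1, g, training=False)
                arr[idx] = orig - eps
                lm, _ = _loss_and_grads(model, feats, 1, g, training=False)
                arr[idx] = orig
                num = (lp - lm) / (2 * eps)
                assert grads[name][idx] == pytest.approx(num, abs=1e-5), name

    def test_instance_loss_weight_zero_is_pure_bag_loss(self, rng):
        feats = rng.normal(size=(6, 16))
        g = np.random.default_rng(0)
        m0 = fresh_model(seed=5, dropout=0.0, instance_loss_weight=0.0)
        m1 = fresh_model(seed=5, dropout=0.0, instance_loss_weight=0.3)
        m1.params = {k: v.copy() for k, v in m0.params.items()}
        l0, _ = _loss_and_grads(m0, feats, 0, g, training=False)
        l1, _ = _loss_and_grads(m1, feats, 0, g, training=False)
        # with zero instance-classifier weights the clustering term is ln 2
        assert l1 == pytest.approx(l0 + 0.3 * np.log(2.0))


class TestSplits:
    def test_sizes_and_partition(self):
        ids = [f"d{i}" for i in range(100)]
        labels = [i % 2 for i in range(100)]
        plan = make_splits(ids, labels, n_folds=10, seed=1)
        assert len(plan.folds) == 10
        for fold in plan.folds:
            tr, va, te = (set(fold[p]) for p in ("train", "val", "test"))
            assert len(tr) == 80 and len(va) == 10 and len(te) == 10
            assert not (tr & va) and not (tr & te) and not (va & te)
            assert tr | va | te == set(ids)

    def test_stratification_within_one_donor(self):
        ids = [f"d{i}" for i in range(61)]
        labels = [1 if i < 25 else 0 for i in range(61)]
        plan = make_splits(ids, labels, n_folds=5, seed=2)
        overall = 25 / 61
        positives = set(ids[:25])
        for fold in plan.folds:
            for part, frac in zip(("train", "val", "test"), (0.8, 0.1, 0.1)):
                members = fold[part]
                n_pos = len(positives & set(members))
                assert abs(n_pos - overall * len(members)) <= 1

    def test_small_class_rejected(self):
        with pytest.raises(ValueError):
            make_splits(["a", "b", "c", "d"], [1, 1, 0, 0])

    def test_deterministic_under_seed(self):
        ids = [f"d{i}" for i in range(30)]
        labels = [i % 2 for i in range(30)]
        assert make_splits(ids, labels, seed=7).folds == make_splits(ids, labels, seed=7).folds


def _separable_bags(rng, n=24, k=6, dim=12):
    """Bags whose mean feature shifts with the label: linearly separable."""
    bags, labels = [], []
    for i in range(n):
        y = i % 2
        feats = rng.normal(size=(k, dim)) + (2.0 * y) * np.eye(dim)[0]
        bags.append(make_bag(feats, donor_id=f"d{i}"))
        labels.append(y)
    return bags, np.array(labels)


class TestTrain:
    def test_loss_decreases_on_separable_data(self, rng):
        bags, labels = _separable_bags(rng)
        cfg = MILConfig(embed_dim=8, attn_dim=6, max_epochs=30, patience=30,
                        dropout=0.0, lr=1e-3)
        g = np.random.default_rng(0)
        model0 = AttentionMILModel.init(12, cfg, seed=1)
        init_loss = np.mean([
            _loss_and_grads(model0, b.features, y, g, training=False)[0]
            for b, y in zip(bags, labels)])
        model = train(bags, labels, list(range(20)), [20, 21, 22, 23], cfg, seed=1)
        final_loss = np.mean([
            _loss_and_grads(model, b.features, y, g, training=False)[0]
            for b, y in zip(bags, labels)])
        assert final_loss < init_loss
        assert model.trained

    def test_single_class_training_rejected(self, rng):
        bags, labels = _separable_bags(rng, n=8)
        with pytest.raises(ValueError):
            train(bags, np.ones_like(labels), list(range(6)), [6, 7])

    def test_roundtrip_serialization(self, rng, tmp_path):
        bags, labels = _separable_bags(rng, n=12)
        cfg = MILConfig(embed_dim=8, attn_dim=6, max_epochs=3, patience=3)
        model = train(bags, labels, list(range(8)), [8, 9, 10, 11], cfg, seed=2)
        model.save(tmp_path / "m")
        loaded = AttentionMILModel.load(tmp_path / "m")
        p0 = predict_slide(bags[0], model)
        assert predict_slide(bags[0], loaded) == pytest.approx(p0)


class TestEvaluate:
    def test_perfect_separation(self):
        assert auc_score([1, 1, 0, 0], [0.9, 0.8, 0.7, 0.6]) == 1.0

    def test_interleaved(self):
        # 3 of the 4 label-discordant pairs are concordant in score
        assert auc_score([1, 0, 1, 0], [0.9, 0.8, 0.7, 0.6]) == 0.75

    def test_ties_count_half(self):
        assert auc_score([1, 0], [0.5, 0.5]) == 0.5

    def test_single_class_test_set_rejected(self, rng):
        model = fresh_model()
        model.trained = True
        bags = [make_bag(rng.normal(size=(2, 16))) for _ in range(3)]
        with pytest.raises(ValueError):
            evaluate(model, bags, [1, 1, 1])

    def test_balanced_accuracy_confusion_arithmetic(self):
        # TP=3 FN=1 TN=2 FP=2 -> (0.75 + 0.5) / 2 = 0.625
        probs = [0.9, 0.8, 0.7, 0.2, 0.6, 0.55, 0.3, 0.1]
        labels = [1, 1, 1, 1, 0, 0, 0, 0]
        assert balanced_accuracy(labels, probs) == pytest.approx(0.625)

    def test_constant_classifier_is_chance(self):
        labels = [1, 0, 1, 0, 1]
        probs = [0.5] * 5
        assert auc_score(labels, probs) == 0.5
        assert balanced_accuracy(labels, probs) == 0.5


class TestAggregate:
    def _fold(self, auc, bacc=0.5):
        return FoldEval(auc=auc, balanced_accuracy=bacc,
                        fpr=np.array([0.0, 1.0]), tpr=np.array([0.0, 1.0]),
                        n_test=10)

    def test_wilcoxon_all_above_chance(self):
        aucs = 0.5 + np.linspace(0.01, 0.10, 10)
        res = wilcoxon_vs_null(aucs)
        assert res["W"] == 55
        assert res["z"] == pytest.approx(2.752, abs=1e-3)
        assert res["p"] == pytest.approx(0.0059, abs=3e-4)
        # scipy as independent cross-check (normal approx. + correction)
        sp = scipy.stats.wilcoxon(aucs - 0.5, correction=True, method="approx")
        assert res["p"] == pytest.approx(sp.pvalue, rel=1e-6)

    def test_symmetric_aucs_null(self):
        aucs = [0.45, 0.55, 0.4, 0.6, 0.48, 0.52]
        assert wilcoxon_vs_null(aucs)["p"] == pytest.approx(1.0, abs=0.05)

    def test_averaged_roc_of_identical_curves(self):
        fpr = np.array([0.0, 0.2, 1.0])
        tpr = np.array([0.0, 0.8, 1.0])
        folds = [FoldEval(0.8, 0.7, fpr, tpr, 10) for _ in range(3)]
        res = aggregate_folds(folds)
        np.testing.assert_allclose(
            res.roc_mean_tpr, np.interp(res.roc_fpr_grid, fpr, tpr))

    def test_best_fold_by_mean_of_auc_and_bacc(self):
        folds = [self._fold(0.6, 0.55), self._fold(0.9, 0.5), self._fold(0.7, 0.75)]
        res = aggregate_folds(folds)
        assert res.best_fold == 2  # (0.7+0.75)/2 beats (0.9+0.5)/2

    def test_needs_two_folds(self):
        with pytest.raises(ValueError):
            aggregate_folds([self._fold(0.6)])
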