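"""Gated attention-MIL model: algebraic invariants, gradients, CV, AUROC."""

import numpy as np
import pytest

from lauren_mil.attmil import (
    AttMILConfig,
    AttMILModel,
    _train_single,
    assign_folds,
    classify,
    evaluate_auroc,
    train_crossval,
)
from lauren_mil.synthetic import DIFFUSE, INTESTINAL

from conftest import gaussian_bags


def small_model(dim=8, seed=0):
    return AttMILModel(AttMILConfig(dim=dim, hidden=6, attention=4), seed=seed)


class TestAttentionScores:
    def test_weights_are_a_distribution(self, rng):
        m = small_model()
        a = m.attention_scores(rng.normal(size=(9, 8)))
        assert np.all(a >= 0)
        assert abs(a.sum() - 1.0) < 1e-6

    def test_single_tile_gets_full_weight(self, rng):
        m = small_model()
        assert m.attention_scores(rng.normal(size=(1, 8)))[0] == pytest.approx(1.0)

    def test_duplicated_tiles_share_weight_equally(self, rng):
        m = small_model()
        row = rng.normal(size=8)
        a = m.attention_scores(np.stack([row, row, row]))
        assert np.allclose(a, 1.0 / 3.0)

    def test_empty_bag_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            small_model().attention_scores(np.empty((0, 8)))


class TestForward:
    def test_permutation_invariance_exact(self, rng):
        m = small_model()
        X = rng.normal(size=(12, 8))
        perm = rng.permutation(12)
        assert np.array_equal(m.forward(X), m.forward(X[perm]))

    def test_zero_classifier_gives_uniform_probabilities(self, rng):
        m = small_model()
        m.params["Wc"][:] = 0.0
        m.params["bc"][:] = 0.0
        assert np.allclose(m.forward(rng.normal(size=(5, 8))), 0.5)

    def test_single_tile_bag_equals_classifier_of_embedding(self, rng):
        m = small_model()
        x = rng.normal(size=(1, 8))
        h = m._embed(x)[0]
        logits = h @ m.params["Wc"] + m.params["bc"]
        expected = np.exp(logits - logits.max())
        expected /= expected.sum()
        assert np.allclose(m.forward(x), expected)

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="dim"):
            small_model().forward(rng.normal(size=(3, 5)))


class TestGradients:
    def test_analytic_gradients_match_finite_differences(self, rng):
        """Backprop through embedding, gated attention, softmax pooling,
        classifier and instance head agrees with central differences."""
        m = small_model(seed=3)
        X = rng.normal(size=(6, 8))
        _, grads = m.loss_and_grads(X, 1, class_weight=1.3)
        eps = 1e-6
        for name, value in m.params.items():
            if name == "bw":  # softmax shift invariance: gradient exactly 0
                assert np.allclose(grads[name], 0.0, atol=1e-12)
                continue
            num = np.zeros_like(value)
            it = np.nditer(value, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                orig = value[idx]
                value[idx] = orig + eps
                lp = m.total_loss(X, 1, 1.3)
                value[idx] = orig - eps
                lm = m.total_loss(X, 1, 1.3)
                value[idx] = orig
                num[idx] = (lp - lm) / (2 * eps)
            scale = max(np.max(np.abs(num)), 1e-8)
            assert np.max(np.abs(num - grads[name])) / scale < 1e-5, name


class TestTraining:
    def test_loss_decreases_on_separable_bags(self):
        bags, labels = gaussian_bags(n_bags=24, seed=1)
        model = _train_single(
            bags,
            [labels[b.slide_id] for b in bags],
            AttMILConfig(dim=16, hidden=16, attention=8, val_fraction=0.0,
                         epochs=12),
            seed=0,
        )
        losses = model.history["train_loss"]
        assert losses[-1] < losses[0]

    def test_training_requires_both_classes(self):
        bags, _ = gaussian_bags(n_bags=6, seed=2)
        with pytest.raises(ValueError, match="both classes"):
            _train_single(bags, [INTESTINAL] * 6, AttMILConfig(dim=16), seed=0)

    def test_training_is_deterministic(self):
        bags, labels = gaussian_bags(n_bags=16, seed=3)
        y = [labels[b.slide_id] for b in bags]
        cfg = AttMILConfig(dim=16, hidden=8, attention=4, epochs=4, restarts=2)
        from lauren_mil.attmil import train_model

        m1 = train_model(bags, y, cfg, seed=5)
        m2 = train_model(bags, y, cfg, seed=5)
        for k in m1.params:
            assert np.array_equal(m1.params[k], m2.params[k])


class TestCrossValidation:
    def test_every_case_predicted_exactly_once(self, small_cohort_run):
        ids = [p.case_id for p in small_cohort_run.cv.predictions]
        assert sorted(ids) == sorted(b.slide_id for b in small_cohort_run.bags)

    def test_folds_partition_and_stratify(self):
        ids = [f"c{i}" for i in range(40)]
        labels = [DIFFUSE if i % 4 == 0 else INTESTINAL for i in range(40)]
        folds = assign_folds(ids, labels, n_folds=5, seed=0)
        assert sorted(folds.mapping) == sorted(ids)
        for f in range(5):
            fold_ids = folds.cases_in(f)
            n_diff = sum(labels[ids.index(c)] == DIFFUSE for c in fold_ids)
            assert abs(n_diff - 10 / 5) <= 1  # 10 diffuse over 5 folds +/- 1

    def test_fold_missing_a_class_fails_before_training(self):
        bags, labels = gaussian_bags(n_bags=10, seed=4)
        # one lone diffuse case cannot be present in every fold
        lone = {b.slide_id: INTESTINAL for b in bags}
        lone[bags[0].slide_id] = DIFFUSE
        with pytest.raises(ValueError, match="missing a class"):
            train_crossval(bags, lone, AttMILConfig(dim=16), seed=0)

    def test_separable_cohort_reaches_high_auroc(self, small_cohort_run):
        assert small_cohort_run.cv.mean_auroc >= 0.85


class TestAUROC:
    def test_perfect_ranking_scores_one(self):
        assert evaluate_auroc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_textbook_four_pair_example(self):
        # positives {0.9, 0.4}, negatives {0.5, 0.1}: wins 3 of 4 pairs
        assert evaluate_auroc([0.9, 0.4, 0.5, 0.1], [1, 1, 0, 0]) == 0.75

    def test_all_ties_score_half(self):
        assert evaluate_auroc([0.5] * 6, [1, 0, 1, 0, 1, 0]) == 0.5

    def test_matches_brute_force_pairwise_oracle(self, rng):
        """Rank implementation equals explicit pairwise win counting on 50
        random score sets with ties."""
        for _ in range(50):
            n = int(rng.integers(4, 15))
            scores = np.round(rng.random(n), 1)  # coarse grid forces ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            pos, neg = scores[labels == 1], scores[labels == 0]
            wins = sum(
                1.0 if p > q else 0.5 if p == q else 0.0
                for p in pos for q in neg
            )
            oracle = wins / (len(pos) * len(neg))
            assert evaluate_auroc(scores, labels) == pytest.approx(oracle)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            evaluate_auroc([0.1, 0.9], [1, 1])


class TestClassify:
    @pytest.mark.parametrize(
        "prob,expected",
        [(0.5, DIFFUSE), (0.0, INTESTINAL), (1.0, DIFFUSE), (0.49, INTESTINAL)],
    )
    def test_threshold_convention(self, prob, expected):
        assert classify(prob) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify(1.5)
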