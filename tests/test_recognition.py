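import copy

import numpy as np
import pytest

from dietvision.recognition import (
    LEVELS,
    HierarchicalClassifier,
    TaxonomyError,
    TrainConfig,
    build_model,
    compare_joint_vs_independent,
    joint_loss,
    load_taxonomy,
    topk_accuracy,
    toy_taxonomy,
    train,
    weighted_inference,
)
from dietvision.scene import make_classification_set


def prob_vec(p, n=20):
    v = np.full(n, (1.0 - p) / (n - 1))
    v[0] = p
    return v


class TestTaxonomy:
    def test_toy_file_round_trip(self, tmp_path):
        tax = toy_taxonomy(6, 3, 2)
        path = tmp_path / "tax.csv"
        tax.write(path)
        back = load_taxonomy(path)
        assert back.fine_names == tax.fine_names
        assert back.fine_to_hyper2 == tax.fine_to_hyper2
        assert back.hyper2_to_hyper1 == tax.hyper2_to_hyper1

    def test_three_row_file(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text(
            "fine,hyper2,hyper1,nutrient_key\n"
            "a,g1,s1,a\nb,g1,s1,b\nc,g2,s1,c\n"
        )
        tax = load_taxonomy(path)
        assert tax.level_sizes == (1, 2, 3)

    def test_empty_hyper1_rejected(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("fine,hyper2,hyper1,nutrient_key\na,g1,,a\n")
        with pytest.raises(TaxonomyError, match="hyper1"):
            load_taxonomy(path)

    def test_duplicate_fine_rejected(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text(
            "fine,hyper2,hyper1,nutrient_key\na,g1,s1,a\na,g1,s1,a\n"
        )
        with pytest.raises(TaxonomyError, match="duplicate"):
            load_taxonomy(path)

    def test_conflicting_parents_rejected(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text(
            "fine,hyper2,hyper1,nutrient_key\na,g1,s1,a\nb,g1,s2,b\n"
        )
        with pytest.raises(TaxonomyError, match="two hyper1"):
            load_taxonomy(path)

    def test_lifting_fine_prediction_is_consistent(self, taxonomy):
        # hierarchy consistency: mapping any fine index up the tree always
        # gives the parents recorded in its path
        for k in range(len(taxonomy.fine_names)):
            h1, h2, fine = taxonomy.path(k)
            assert taxonomy.hyper2_names[taxonomy.hyper2_index_of_fine(k)] == h2
            assert taxonomy.hyper1_names[taxonomy.hyper1_index_of_fine(k)] == h1


class TestModel:
    def test_head_widths_match_taxonomy(self):
        tax = toy_taxonomy(4, 3, 2)
        model = build_model(tax)
        assert model.head_sizes == (2, 3, 4)  # coarse to fine

    def test_forward_probabilities_sum_to_one(self, taxonomy):
        model = build_model(taxonomy, seed=1)
        rng = np.random.default_rng(0)
        probs = model.predict_proba(rng.uniform(0, 1, (3, 16, 16, 3)))
        for p in probs:
            assert np.allclose(p.sum(axis=1), 1.0, atol=1e-9)

    def test_eval_determinism(self, taxonomy):
        model = build_model(taxonomy, seed=1)
        img = np.random.default_rng(0).uniform(0, 1, (2, 16, 16, 3))
        a = model.predict_proba(img)
        b = model.predict_proba(img)
        for x, y in zip(a, b):
            assert np.array_equal(x, y)

    def test_save_load_round_trip(self, taxonomy, tmp_path):
        model = build_model(taxonomy, seed=1)
        path = tmp_path / "model.npz"
        model.save(path)
        other = build_model(taxonomy, seed=99)
        other.load(path)
        img = np.random.default_rng(0).uniform(0, 1, (2, 16, 16, 3))
        for x, y in zip(model.predict_proba(img), other.predict_proba(img)):
            assert np.allclose(x, y)


class TestTrain:
    def test_smoke_reaches_90_percent_fine(self, taxonomy):
        model = build_model(taxonomy, seed=0)
        ds = make_classification_set(taxonomy, n_per_class=48, seed=0)
        log = train(model, ds, TrainConfig(seed=0))
        assert log.accuracy[-1]["fine"] >= 0.9
        assert len(log.loss) == 20

    def test_zero_learning_rate_leaves_weights(self, taxonomy):
        model = build_model(taxonomy, seed=0)
        before = [w.copy() for w in model.parameters()]
        ds = make_classification_set(taxonomy, n_per_class=2, seed=0)
        train(model, ds, TrainConfig(learning_rate=0.0, epochs=1, seed=0))
        for b, a in zip(before, model.parameters()):
            assert np.array_equal(b, a)

    def test_loss_linearity_in_level_weights(self, taxonomy):
        model = build_model(taxonomy, seed=0)
        ds = make_classification_set(taxonomy, n_per_class=2, seed=0)
        probs = model.predict_proba(ds.images)
        y = np.stack([ds.hyper1_idx, ds.hyper2_idx, ds.fine_idx], axis=1)
        full = joint_loss(probs, y, (1.0, 1.0, 1.0))
        no_fine = joint_loss(probs, y, (1.0, 1.0, 0.0))
        fine_only = joint_loss(probs, y, (0.0, 0.0, 1.0))
        assert full == pytest.approx(no_fine + fine_only, rel=1e-12)

    def test_labels_outside_taxonomy_rejected(self, taxonomy):
        model = build_model(taxonomy, seed=0)
        ds = make_classification_set(taxonomy, n_per_class=2, seed=0)
        bad = copy.copy(ds)
        bad.fine_idx = ds.fine_idx.copy()
        bad.fine_idx[0] = 99
        with pytest.raises(TaxonomyError):
            train(model, bad, TrainConfig(epochs=1))

    def test_seeded_training_reproducible(self, taxonomy):
        ds = make_classification_set(taxonomy, n_per_class=4, seed=0)
        m1 = build_model(taxonomy, seed=3)
        m2 = build_model(taxonomy, seed=3)
        train(m1, ds, TrainConfig(epochs=2, seed=5))
        train(m2, ds, TrainConfig(epochs=2, seed=5))
        for a, b in zip(m1.parameters(), m2.parameters()):
            assert np.array_equal(a, b)


class TestWeightedInference:
    def test_dominant_fine(self):
        rs = weighted_inference(
            [prob_vec(0.6), prob_vec(0.5), prob_vec(0.9)], (1, 1, 1), 0.0
        )
        assert rs.chosen_level == "fine"
        assert rs.chosen_confidence == pytest.approx(0.9)

    def test_hyper_fallback(self):
        rs = weighted_inference(
            [prob_vec(0.7), prob_vec(0.8), prob_vec(0.2)], (1, 1, 1), 0.5
        )
        assert rs.chosen_level == "hyper2"

    def test_matches_brute_force_enumeration(self):
        # oracle: direct enumeration of the decision rule on a 0.05 grid
        grid = np.round(np.arange(0.05, 1.0001, 0.05), 2)
        weights = (1.0, 0.8, 1.2)
        thr = 0.5
        for p1 in grid:
            for p2 in grid:
                for p3 in grid:
                    rs = weighted_inference(
                        [prob_vec(p1), prob_vec(p2), prob_vec(p3)], weights, thr
                    )
                    # brute-force rule
                    conf = {
                        "hyper1": weights[0] * p1,
                        "hyper2": weights[1] * p2,
                        "fine": weights[2] * p3,
                    }
                    cands = ["hyper1", "hyper2", "fine"]
                    if p3 < thr:
                        cands.remove("fine")
                    top = max(conf[lv] for lv in cands)
                    # ties break toward the finer level
                    best = [lv for lv in cands if conf[lv] >= top - 1e-12][-1]
                    assert rs.chosen_level == best, (p1, p2, p3)

    def test_scale_invariance_of_weights(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            ps = rng.uniform(0.05, 1.0, 3)
            w = rng.uniform(0.1, 2.0, 3)
            a = weighted_inference([prob_vec(p) for p in ps], tuple(w), 0.5)
            b = weighted_inference([prob_vec(p) for p in ps], tuple(w * 7.3), 0.5)
            assert a.chosen_level == b.chosen_level
            assert a.chosen_index == b.chosen_index

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            weighted_inference([prob_vec(0.5)] * 3, (0.0, 0.0, 0.0), 0.5)

    def test_unnormalized_probs_rejected(self):
        bad = np.full(10, 0.2)
        with pytest.raises(ValueError):
            weighted_inference([prob_vec(0.5), prob_vec(0.5), bad], (1, 1, 1), 0.5)


class TestTopkAccuracy:
    def test_perfect_model_scores_one(self, taxonomy, trained_model):
        ds = make_classification_set(taxonomy, n_per_class=8, seed=0)
        table = topk_accuracy(trained_model, ds, k=3)
        assert table["fine"]["top1"] == 1.0
        assert table["hyper2"]["top3"] == 1.0

    def test_k_equal_to_classes_is_one(self, taxonomy):
        model = build_model(taxonomy, seed=7)  # untrained
        ds = make_classification_set(taxonomy, n_per_class=2, seed=0)
        k = len(taxonomy.fine_names)
        table = topk_accuracy(model, ds, k=k)
        assert table["fine"][f"top{k}"] == 1.0

    def test_uniform_model_hits_chance(self):
        tax = toy_taxonomy(4, 4, 4)

        class Uniform(HierarchicalClassifier):
            def predict_proba(self, images):
                n = len(images)
                return [np.full((n, c), 1.0 / c) for c in self.head_sizes]

        model = Uniform(tax)
        ds = make_classification_set(tax, n_per_class=10, seed=0)
        table = topk_accuracy(model, ds, k=1)
        # deterministic argmax tie-break picks class 0: chance level exactly
        assert table["fine"]["top1"] == pytest.approx(0.25)

    def test_invalid_k(self, taxonomy, trained_model):
        ds = make_classification_set(taxonomy, n_per_class=2, seed=0)
        with pytest.raises(ValueError):
            topk_accuracy(trained_model, ds, k=0)


def test_compare_joint_vs_independent_reports_tables():
    tax = toy_taxonomy(6, 3, 2)
    ds = make_classification_set(tax, n_per_class=12, seed=0)
    cfg = TrainConfig(epochs=5, seed=0)
    out = compare_joint_vs_independent(tax, ds, cfg)
    for kind in ("joint", "independent"):
        assert set(out[kind]) == set(LEVELS)
        for lv in LEVELS:
            assert 0.0 <= out[kind][lv]["top1"] <= 1.0
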