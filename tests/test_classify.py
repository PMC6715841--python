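"""SVM / CNN training protocol, learning curves, confusion matrices."""

import numpy as np
import pytest

import crif
from crif.classify import (
    ConfusionMatrix,
    evaluate,
    learning_curve,
    mixed_stage_protocol,
    multiclass_protocol,
    per_class_accuracy,
    split_train_test,
    train_cnn,
    train_svm,
)
from crif.datasets import (
    GROWTH_STAGES,
    P_POLYMYXA_REPORTED_ACCURACY,
    P_PUTIDA_REPORTED_ACCURACY,
    growth_stage_confusion_matrices,
)
from crif.simulate import stage_variants


@pytest.fixture(scope="module")
def pooled(two_class_catalogs):
    a, b = two_class_catalogs
    return crif.merge_catalogs([a, b])


class TestSplitTrainTest:
    def test_complement_property(self, cfg, signatures):
        cat = crif.sample_catalog(signatures["pseudomonas_like"], 60, cv=0.1, seed=1, config=cfg)
        train, test = split_train_test(cat, n_train=10, n_test=50, seed=0)
        train_ids = {e.cell_id for e in train.entries}
        test_ids = {e.cell_id for e in test.entries}
        assert not train_ids & test_ids
        assert train_ids | test_ids == {e.cell_id for e in cat.entries}

    def test_deterministic(self, pooled):
        s1 = split_train_test(pooled, 20, 50, seed=5)
        s2 = split_train_test(pooled, 20, 50, seed=5)
        for a, b in zip(s1, s2):
            assert [e.cell_id for e in a.entries] == [e.cell_id for e in b.entries]

    def test_inclusion_frequency_roughly_uniform(self, cfg, signatures):
        cat = crif.sample_catalog(signatures["pseudomonas_like"], 20, cv=0.1, seed=2, config=cfg)
        counts = np.zeros(20)
        reps = 400
        for s in range(reps):
            train, _ = split_train_test(cat, n_train=5, n_test=5, seed=s)
            for e in train.entries:
                counts[e.cell_id - 1] += 1
        p = 5 / 20
        sd = np.sqrt(reps * p * (1 - p))
        assert np.all(np.abs(counts - reps * p) <= 3.5 * sd)

    def test_insufficient_population_rejected(self, cfg, signatures):
        cat = crif.sample_catalog(signatures["pseudomonas_like"], 30, cv=0.1, seed=3, config=cfg)
        with pytest.raises(ValueError, match="needs"):
            split_train_test(cat, n_train=10, n_test=50, seed=0)


class TestSVM:
    def test_memorizes_single_training_point_per_class(self, pooled):
        train, _ = split_train_test(pooled, n_train=1, n_test=0, seed=1)
        model = train_svm(train)
        acc, _ = evaluate(model, train)
        assert acc == 1.0

    def test_separable_fixture_high_accuracy(self, pooled):
        train, test = split_train_test(pooled, n_train=100, n_test=50, seed=2)
        model = train_svm(train)
        acc, _ = evaluate(model, test)
        assert acc >= 0.95

    def test_shuffled_labels_near_chance(self, cfg, signatures):
        # identical class signatures + permuted labels => no signal
        a = crif.sample_catalog(signatures["pseudomonas_like"], 200, cv=0.1, seed=4, config=cfg)
        rng = np.random.default_rng(0)
        accs = []
        for rep in range(20):
            labels = list(rng.permutation(["x"] * 100 + ["y"] * 100))
            cat = crif.HyperspectrumCatalog(a.entries, labels, cfg)
            train, test = split_train_test(cat, n_train=30, n_test=50, seed=rep)
            acc, _ = evaluate(train_svm(train), test)
            accs.append(acc)
        assert abs(np.mean(accs) - 0.5) < 0.1

    def test_single_class_rejected(self, cfg, signatures):
        cat = crif.sample_catalog(signatures["pseudomonas_like"], 10, cv=0.1, seed=5, config=cfg)
        with pytest.raises(ValueError, match="class"):
            train_svm(cat)


class TestCNN:
    def test_separable_fixture_high_accuracy(self, pooled):
        train, test = split_train_test(pooled, n_train=100, n_test=50, seed=3)
        model = train_cnn(train, epochs=5, seed=0)
        acc, _ = evaluate(model, test)
        assert acc >= 0.9

    def test_untrained_network_at_chance_against_shuffled_labels(self, pooled, cfg):
        # an untrained net's fixed predictions score ~1/2 on balanced labels
        # drawn independently of the input
        train, test = split_train_test(pooled, n_train=50, n_test=50, seed=4)
        model = train_cnn(train, epochs=0, seed=0)
        rng = np.random.default_rng(0)
        accs = []
        for _ in range(30):
            shuffled = crif.HyperspectrumCatalog(
                test.entries, list(rng.permutation(test.labels)), cfg
            )
            acc, _ = evaluate(model, shuffled)
            accs.append(acc)
        assert abs(np.mean(accs) - 0.5) < 0.1

    def test_deterministic_given_seed(self, pooled):
        train, test = split_train_test(pooled, n_train=30, n_test=50, seed=5)
        p1 = train_cnn(train, epochs=2, seed=7).predict(test)
        p2 = train_cnn(train, epochs=2, seed=7).predict(test)
        assert p1 == p2


class TestEvaluate:
    def test_perfect_predictions_diagonal(self, pooled):
        train, test = split_train_test(pooled, n_train=100, n_test=50, seed=6)
        model = train_svm(train)
        acc, cm = evaluate(model, test)
        if acc == 1.0:
            assert np.array_equal(cm.counts, np.diag(cm.counts.diagonal()))
        assert cm.accuracy == pytest.approx(acc)

    def test_counting_oracle(self, pooled):
        train, test = split_train_test(pooled, n_train=10, n_test=50, seed=7)
        model = train_svm(train)
        acc, cm = evaluate(model, test)
        predictions = model.predict(test)
        direct = sum(p == t for p, t in zip(predictions, test.labels)) / len(test)
        assert acc == pytest.approx(direct)
        assert cm.counts.sum() == len(test)
        # columns are true classes
        for j, cls in enumerate(cm.classes):
            assert cm.column_sums()[j] == test.labels.count(cls)

    def test_empty_test_rejected(self, pooled, cfg):
        train, _ = split_train_test(pooled, n_train=10, n_test=0, seed=8)
        model = train_svm(train)
        with pytest.raises(ValueError):
            evaluate(model, crif.HyperspectrumCatalog([], [], cfg))


class TestLearningCurve:
    def test_noise_free_fixture_is_perfect_at_all_n(self, cfg, signatures):
        a = crif.sample_catalog(signatures["pseudomonas_like"], 300, cv=0.0, seed=1, config=cfg)
        b = crif.sample_catalog(signatures["paenibacillus_like"], 300, cv=0.0, seed=2, config=cfg)
        lc = learning_curve([a, b], "svm", n_list=(2, 10), repeats=3, seed=0)
        assert np.all(lc.mean_accuracy == 1.0)
        assert np.all(lc.sd_accuracy == 0.0)

    def test_mean_accuracy_nondecreasing_within_sd(self, pooled):
        lc = learning_curve(pooled, "svm", n_list=(2, 10, 50, 100), repeats=5, seed=1)
        for i in range(len(lc.n_train) - 1):
            assert lc.mean_accuracy[i + 1] >= lc.mean_accuracy[i] - lc.sd_accuracy[i]

    def test_repeats_share_expected_value(self, pooled):
        lc1 = learning_curve(pooled, "svm", n_list=(50,), repeats=1, seed=2)
        lc30 = learning_curve(pooled, "svm", n_list=(50,), repeats=30, seed=3)
        spread = max(lc30.sd_accuracy[0], 0.01)
        assert abs(lc1.mean_accuracy[0] - lc30.mean_accuracy[0]) <= 4 * spread


class TestPerClassAccuracy:
    def test_reproduces_published_accuracy_rows(self):
        matrices = growth_stage_confusion_matrices()
        for name, reported in [
            ("P. putida", P_PUTIDA_REPORTED_ACCURACY),
            ("P. polymyxa", P_POLYMYXA_REPORTED_ACCURACY),
        ]:
            acc = per_class_accuracy(matrices[name], rounded=True)
            assert [acc[s] for s in GROWTH_STAGES] == reported

    def test_exact_ratios(self):
        cm = growth_stage_confusion_matrices()["P. putida"]
        acc = per_class_accuracy(cm)
        assert acc["52 h"] == pytest.approx(20 / 23)
        assert acc["6 h"] == pytest.approx(17 / 31)

    def test_identity_matrix_all_ones(self):
        cm = ConfusionMatrix(np.eye(3, dtype=int) * 5, ["a", "b", "c"])
        assert all(v == 1.0 for v in per_class_accuracy(cm).values())

    def test_zero_column_rejected(self):
        counts = np.array([[2, 0], [1, 0]])
        with pytest.raises(ValueError):
            per_class_accuracy(ConfusionMatrix(counts, ["a", "b"]))


class TestMulticlassProtocol:
    def test_six_distinct_stages_diagonal_dominant(self, cfg, signatures):
        variants = stage_variants(signatures["pseudomonas_like"], 6,
                                  peak_drift_nm=40, amp_drift=0.8, config=cfg)
        stage_catalogs = {
            v.class_name: crif.sample_catalog(v, 80, cv=0.05, seed=10 + i, config=cfg)
            for i, v in enumerate(variants)
        }
        cm, acc = multiclass_protocol(stage_catalogs, "svm", n_train=40, n_test=30, seed=0)
        assert all(v > 0.8 for v in acc.values())
        assert np.all(np.diag(cm.counts) >= cm.counts.sum(axis=0) * 0.8)

    def test_identical_stages_confuse_each_other(self, cfg, signatures):
        sig_a = signatures["pseudomonas_like"]
        sig_c = signatures["paenibacillus_like"]
        stage_catalogs = {
            "twin1": crif.sample_catalog(sig_a, 80, cv=0.05, seed=1, config=cfg),
            "twin2": crif.sample_catalog(sig_a, 80, cv=0.05, seed=2, config=cfg),
            "other": crif.sample_catalog(sig_c, 80, cv=0.05, seed=3, config=cfg),
        }
        cm, _ = multiclass_protocol(stage_catalogs, "svm", n_train=30, n_test=30, seed=0)
        idx = {c: i for i, c in enumerate(cm.classes)}
        t1, t2, other = idx["twin1"], idx["twin2"], idx["other"]
        # errors in each twin's column land in the other twin's row, not in "other"
        for col in (t1, t2):
            assert cm.counts[other, col] <= 3
        assert cm.counts[t1, t2] + cm.counts[t2, t1] >= 10  # twins split between each other

    def test_column_sums_equal_test_counts(self, cfg, signatures):
        variants = stage_variants(signatures["pseudomonas_like"], 3,
                                  peak_drift_nm=30, config=cfg)
        stage_catalogs = {
            v.class_name: crif.sample_catalog(v, 30, cv=0.05, seed=20 + i, config=cfg)
            for i, v in enumerate(variants)
        }
        cm, _ = multiclass_protocol(stage_catalogs, "svm", n_train=10, n_test=1, seed=0)
        assert np.all(cm.column_sums() == 1)


class TestMixedStageProtocol:
    def _species_stage_catalogs(self, cfg, signatures, n=110, seed0=30):
        out = {}
        for s, species in enumerate(["pseudomonas_like", "paenibacillus_like"]):
            variants = stage_variants(signatures[species], 3, config=cfg)
            out[species] = {
                f"stage{i}": crif.sample_catalog(v, n, cv=0.1, seed=seed0 + 10 * s + i, config=cfg)
                for i, v in enumerate(variants)
            }
        return out

    def test_species_separated_all_stages_accurate(self, cfg, signatures):
        catalogs = self._species_stage_catalogs(cfg, signatures)
        accs = mixed_stage_protocol(catalogs, "svm", n_train_per_stage=50, n_test=50, seed=0)
        assert set(accs) == {"stage0", "stage1", "stage2"}
        assert all(v >= 0.85 for v in accs.values())

    def test_identical_species_near_chance(self, cfg, signatures):
        variants = stage_variants(signatures["pseudomonas_like"], 2, config=cfg)
        catalogs = {
            sp: {
                f"stage{i}": crif.sample_catalog(v, 110, cv=0.1, seed=50 + 10 * s + i, config=cfg)
                for i, v in enumerate(variants)
            }
            for s, sp in enumerate(["speciesA", "speciesB"])
        }
        accs = mixed_stage_protocol(catalogs, "svm", n_train_per_stage=50, n_test=50, seed=0)
        assert all(0.3 <= v <= 0.7 for v in accs.values())
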