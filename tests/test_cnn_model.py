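import numpy as np
import pytest

from regseq_tss import cnn_model as cm
from regseq_tss.sequence_io import EncodedSequence, labels_of

from conftest import make_sequences


def brute_force_auc(labels, scores):
    """Pairwise Mann–Whitney oracle: P(pos > neg) + 0.5 P(tie)."""
    pos = [s for s, z in zip(scores, labels) if z == 1]
    neg = [s for s, z in zip(scores, labels) if z == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestBinaryCrossEntropy:
    def test_perfect_prediction_is_zero(self):
        assert cm.binary_cross_entropy([1, 0], [1.0, 0.0]) == pytest.approx(0.0, abs=1e-10)

    def test_uninformative_half_is_log_two(self):
        assert cm.binary_cross_entropy([1, 0, 1], [0.5] * 3) == pytest.approx(np.log(2))

    def test_hand_computed_example(self):
        assert cm.binary_cross_entropy([1], [0.75]) == pytest.approx(-np.log(0.75))

    def test_length_mismatch_fatal(self):
        with pytest.raises(ValueError):
            cm.binary_cross_entropy([1, 0], [0.5])

    def test_agrees_with_per_sample_summation(self, rng):
        z = rng.integers(0, 2, 50)
        y = rng.uniform(0.01, 0.99, 50)
        by_hand = -sum(zi * np.log(yi) + (1 - zi) * np.log(1 - yi)
                       for zi, yi in zip(z, y)) / 50
        assert cm.binary_cross_entropy(z, y) == pytest.approx(by_hand, abs=1e-10)


class TestAUC:
    def test_perfect_separation(self):
        assert cm.compute_auroc([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1]) == 1.0

    def test_all_tied_scores_give_half(self):
        assert cm.compute_auroc([1, 0, 1, 0], [0.3] * 4) == 0.5

    def test_single_class_fatal(self):
        with pytest.raises(ValueError, match="both classes"):
            cm.compute_auroc([1, 1], [0.1, 0.2])

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 50))
        labels = np.r_[1, 0, rng.integers(0, 2, n - 2)]
        scores = np.round(rng.random(n), 1)  # coarse grid forces ties
        assert cm.compute_auroc(labels, scores) == pytest.approx(
            brute_force_auc(labels, scores), abs=1e-12
        )


class TestSplits:
    def test_cage_row_train_test_counts(self):
        labels = np.r_[np.ones(27_227, int), np.zeros(38_538, int)]
        tr, te = cm.holdout_split(labels, 0.1, np.random.default_rng(0))
        assert (len(tr), len(te)) == (59_189, 6_576)

    def test_us_uu_row_train_test_counts(self):
        labels = np.r_[np.ones(1_884, int), np.zeros(4_978, int)]
        tr, te = cm.holdout_split(labels, 0.1, np.random.default_rng(0))
        assert (len(tr), len(te)) == (6_176, 686)

    def test_split_is_stratified_and_disjoint(self):
        labels = np.r_[np.ones(100, int), np.zeros(300, int)]
        tr, te = cm.holdout_split(labels, 0.1, np.random.default_rng(1))
        assert set(tr).isdisjoint(te) and len(tr) + len(te) == 400
        assert labels[te].sum() == 10  # 10% of each class

    def test_fold_sizes_on_us_uu_train_count(self):
        labels = np.r_[np.ones(1_696, int), np.zeros(4_480, int)]
        folds = cm.stratified_folds(labels, 5, np.random.default_rng(0))
        assert sorted(len(f) for f in folds) == [1235, 1235, 1235, 1235, 1236]
        for f in folds:  # per-class spread <= 1 as well
            assert labels[f].sum() in (339, 340)

    def test_k_below_two_fatal(self):
        with pytest.raises(ValueError):
            cm.stratified_folds(np.array([0, 1]), 1, np.random.default_rng(0))


class TestSweepEnumeration:
    def test_pool_sweep_is_the_seven_coupled_pairs(self):
        pairs = [(s.pool_1, s.pool_2) for s in cm.pool_sweep()]
        assert pairs == [(1, 100), (2, 50), (4, 25), (10, 10), (25, 4), (50, 2), (100, 1)]

    def test_filter_count_sweep(self):
        counts = [s.n_filters_1 for s in cm.filter_count_sweep()]
        assert counts == [30, 60, 90, 120]
        assert all(s.pool_1 == 10 for s in cm.filter_count_sweep())

    def test_filter_size_sweep(self):
        sweep = cm.filter_size_sweep()
        assert [s.filter_size_1 for s in sweep] == [9, 19, 29]
        assert all(s.n_filters_1 == 90 for s in sweep)

    def test_model_naming_convention(self):
        assert cm.ArchitectureSpec(pool_1=10, pool_2=10).name == "CNN-10"
        assert cm.ArchitectureSpec(pool_1=1, pool_2=100).name == "CNN-1"
        assert cm.ArchitectureSpec(n_filters_1=90).name == "CNN-10(90)"
        assert cm.ArchitectureSpec(n_filters_1=90, filter_size_1=9).name == "CNN_9-10(90)"

    def test_family_has_twelve_members(self):
        assert len(cm.sweep_family()) == 12


def separable_toy(n=100, l=100):
    half = n // 2
    seqs = ["G" * l] * half + ["A" * l] * half
    return make_sequences(seqs, [1] * half + [0] * half)


class TestTraining:
    ARCH = cm.ArchitectureSpec(input_length=100)

    def test_separable_toy_reaches_high_training_auc(self):
        data = separable_toy(n=200)
        model = cm.train_model(data, self.ARCH, cm.TrainingSpec(seed=0))
        auc = cm.compute_auroc(labels_of(data), cm.predict(model, data))
        assert auc >= 0.99

    def test_training_is_deterministic_for_fixed_seed(self, small_dataset):
        data = [EncodedSequence(id=s.id, sequence=s.sequence[:100], label=s.label)
                for s in small_dataset.sequences]
        tr = cm.TrainingSpec(epochs=2, seed=5)
        p1 = cm.predict(cm.train_model(data, self.ARCH, tr), data)
        p2 = cm.predict(cm.train_model(data, self.ARCH, tr), data)
        np.testing.assert_array_equal(p1, p2)

    def test_single_class_training_fatal(self):
        data = make_sequences(["ACGT" * 25] * 10, [1] * 10)
        with pytest.raises(ValueError, match="both classes"):
            cm.train_model(data, self.ARCH, cm.TrainingSpec(seed=0))

    def test_length_mismatch_fatal_at_predict(self):
        data = separable_toy(n=20)
        model = cm.train_model(data, self.ARCH, cm.TrainingSpec(epochs=1, seed=0))
        with pytest.raises(ValueError, match="length"):
            cm.predict(model, make_sequences(["A" * 200], [0]))

    def test_duplicated_input_gets_identical_probability(self):
        data = separable_toy(n=20)
        model = cm.train_model(data, self.ARCH, cm.TrainingSpec(epochs=1, seed=0))
        probe = make_sequences(["GATC" * 25] * 2)
        p = cm.predict(model, probe)
        assert p[0] == p[1]

    def test_save_load_round_trip(self, tmp_path):
        data = separable_toy(n=20)
        model = cm.train_model(data, self.ARCH, cm.TrainingSpec(epochs=1, seed=0))
        cm.save_model(model, tmp_path / "m.npz")
        loaded = cm.load_model(tmp_path / "m.npz")
        np.testing.assert_array_equal(cm.predict(model, data),
                                      cm.predict(loaded, data))


class TestCrossValidate:
    def test_report_shape_and_bounds(self):
        data = separable_toy(n=100)
        report = cm.cross_validate(
            data, cm.ArchitectureSpec(input_length=100),
            cm.TrainingSpec(epochs=1, seed=0),
        )
        assert len(report.fold_val_auc) == 5
        assert len(report.fold_holdout_auc) == 5
        assert all(0.0 <= a <= 1.0 for a in report.fold_val_auc)
        assert min(report.fold_val_auc) <= report.mean_val_auc <= max(report.fold_val_auc)
        assert report.combined_auc == pytest.approx(
            0.5 * (report.mean_val_auc + report.mean_holdout_auc)
        )
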