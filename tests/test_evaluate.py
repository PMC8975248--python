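import numpy as np
import pytest

from emgdx import (
    CLASSES,
    INDETERMINATE,
    TrainingConfig,
    compute_metrics,
    cross_validate,
    stratified_kfold,
)
from emgdx.features import FeatureVector

H, M, N = CLASSES


def _toy_features(rng, n_parents_per_class=12, M_factor=9, informative=True):
    """Feature vectors whose fd block encodes the class (or pure noise)."""
    fvs = []
    for ci, cls in enumerate(CLASSES):
        for p in range(n_parents_per_class):
            pid = f"{cls}-{p}"
            for off in range(M_factor):
                fd = rng.normal(size=6)
                if informative:
                    fd[ci] += 8.0
                lbp = np.abs(rng.normal(size=256))
                fvs.append(FeatureVector(fd=fd, lbp=lbp, signal_id=f"{pid}#d{off}",
                                         parent_id=pid, offset=off, label=cls))
    return fvs


def _stub_factory(label_fn):
    """Classifier stub bypassing training; label_fn maps row -> label."""
    def factory(X_tr, y_tr, config, fold_seed):
        return lambda X: np.asarray([label_fn(row) for row in X])
    return factory


class TestStratifiedKfold:
    def test_2250_items_give_folds_of_225(self):
        labels = np.repeat([H, M, N], [1350, 450, 450])
        fa = stratified_kfold(labels, 10, seed=0)
        folds, sizes = np.unique(fa.fold_of, return_counts=True)
        assert len(folds) == 10 and np.all(sizes == 225)
        # exact per-class stratification: 135/45/45 in every fold
        for f in range(10):
            in_fold = labels[fa.fold_of == f]
            assert sorted(np.unique(in_fold, return_counts=True)[1]) == [45, 45, 135]

    def test_k1_rejected(self):
        with pytest.raises(ValueError, match="k must be >= 2"):
            stratified_kfold([H, H, M, M], 1)

    def test_class_smaller_than_k_rejected(self):
        with pytest.raises(ValueError, match="fewer than k"):
            stratified_kfold([H] * 10 + [M] * 2, 5)

    def test_deterministic(self):
        labels = np.repeat([H, M, N], 30)
        a = stratified_kfold(labels, 5, seed=3)
        b = stratified_kfold(labels, 5, seed=3)
        assert np.array_equal(a.fold_of, b.fold_of)


class TestComputeMetrics:
    def test_accuracy_arithmetic(self):
        true = [H] * 10
        dec = [H] * 9 + [M]
        assert compute_metrics(true, dec).accuracy == pytest.approx(90.0)

    def test_sensitivity_specificity_arithmetic(self):
        # class H: TP=3, FN=1, FP=0, TN=6
        true = [H, H, H, H, M, M, M, N, N, N]
        dec = [H, H, H, M, M, M, M, N, N, N]
        m = compute_metrics(true, dec)
        assert m.sensitivity[H] == pytest.approx(75.0)
        assert m.specificity[H] == pytest.approx(100.0)

    def test_indeterminate_row_normalization(self):
        m = compute_metrics([M, M, M], [M, M, INDETERMINATE])
        row = m.confusion_pct[1]
        assert row == pytest.approx([0.0, 200 / 3, 0.0, 100 / 3])

    def test_rows_sum_to_100_with_indeterminate_column(self):
        rng = np.random.default_rng(0)
        true = rng.choice(list(CLASSES), size=200)
        dec = rng.choice(list(CLASSES) + [INDETERMINATE], size=200)
        m = compute_metrics(true, dec)
        assert np.allclose(m.confusion_pct.sum(axis=1), 100.0, atol=1e-6)

    def test_indeterminate_counts_against_accuracy_and_sensitivity(self):
        m = compute_metrics([H, H], [H, INDETERMINATE])
        assert m.accuracy == pytest.approx(50.0)
        assert m.sensitivity[H] == pytest.approx(50.0)
        assert m.specificity[M] == pytest.approx(100.0)  # INDET is a negative for M

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            compute_metrics(["tremor"], [H])
        with pytest.raises(ValueError, match="outside"):
            compute_metrics([H], ["tremor"])


class TestCrossValidate:
    def test_oracle_stub_gives_perfect_scores(self, rng):
        fvs = _toy_features(rng, n_parents_per_class=5, M_factor=3)
        id_of = {tuple(np.round(fv.fused, 6)): fv.label for fv in fvs}
        truth = {fv.signal_id: fv.label for fv in fvs}
        # stub recovers the true label from the embedded fd offset
        factory = _stub_factory(lambda row: CLASSES[int(np.argmax(row[:6]))])
        rep = cross_validate(fvs, k=3, runs=2, seed=0, classifier_factory=factory)
        for run in rep.runs:
            assert run.accuracy == 100.0
            assert run.downsample_accuracy == 100.0
            assert run.indeterminate_pct == 0.0
            assert np.allclose(np.diag(run.confusion_pct[:, :3]), 100.0)

    def test_random_stub_near_chance(self, rng):
        """A uniformly random classifier scores 1/3 per downsampled signal;
        after the strict-majority vote over M=3 labels, the per-recording
        accuracy drops to P(majority exists)/3 = (21/27)/3 = 7/27 because
        all-distinct sequences become indeterminate."""
        fvs = _toy_features(rng, n_parents_per_class=100, M_factor=3, informative=False)

        def rand_label(row, rng=np.random.default_rng(123)):
            return rng.choice(list(CLASSES))

        rep = cross_validate(fvs, k=3, runs=20, seed=1,
                             classifier_factory=_stub_factory(rand_label))
        mean_down, _ = rep.mean_sd(lambda r: r.downsample_accuracy)
        mean_ac, _ = rep.mean_sd(lambda r: r.accuracy)
        assert abs(mean_down - 100.0 / 3) < 5.0
        assert abs(mean_ac - 100.0 * 7 / 27) < 5.0

    def test_counts_of_predictions_and_decisions(self, rng):
        fvs = _toy_features(rng, n_parents_per_class=5, M_factor=4)
        factory = _stub_factory(lambda row: CLASSES[int(np.argmax(row[:6]))])
        rep = cross_validate(fvs, k=3, runs=1, seed=0, classifier_factory=factory)
        assert rep.M == 4
        assert rep.runs[0].confusion_counts.sum() == 15  # one decision per parent

    def test_unequal_children_rejected(self, rng):
        fvs = _toy_features(rng, n_parents_per_class=4, M_factor=3)
        with pytest.raises(ValueError, match="expected M"):
            cross_validate(fvs[:-1], k=2, runs=1, seed=0)

    def test_single_run_has_zero_sd(self, rng):
        fvs = _toy_features(rng, n_parents_per_class=5, M_factor=3)
        factory = _stub_factory(lambda row: CLASSES[int(np.argmax(row[:6]))])
        rep = cross_validate(fvs, k=3, runs=1, seed=0, classifier_factory=factory)
        _, sd = rep.mean_sd(lambda r: r.accuracy)
        assert sd == 0.0

    def test_group_by_parent_mode(self, rng):
        fvs = _toy_features(rng, n_parents_per_class=9, M_factor=3)
        factory = _stub_factory(lambda row: CLASSES[int(np.argmax(row[:6]))])
        rep = cross_validate(fvs, k=3, runs=1, seed=0, group_by_parent=True,
                             classifier_factory=factory)
        assert rep.runs[0].accuracy == 100.0

    def test_real_mlp_beats_chance_on_synthetic_data(self, small_features):
        """Real pipeline features + MLP: well above the 1/3 chance level."""
        rep = cross_validate(small_features, k=3,
                             config=TrainingConfig(n_hidden=10, n_epochs=50),
                             runs=1, seed=0)
        _, _ = rep.mean_sd(lambda r: r.accuracy)
        assert rep.runs[0].downsample_accuracy > 100.0 / 3 + 30.0
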