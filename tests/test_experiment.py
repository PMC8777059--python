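"""Cross-validation protocol: folds, early stopping, epoch selection,
majority voting, and the hyperparameter grid."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import rteeg.experiment as experiment
from rteeg.experiment import (
    CVResult,
    ExperimentError,
    TrainConfig,
    make_folds,
    run_cv,
    run_grid,
    select_epoch,
    train_with_early_stopping,
    trial_majority_vote,
)
from rteeg.models import ModelSpec
from rteeg.validation import ReducedProfile, make_recovery_dataset, recovery_cv

# Desk-scale profiles for protocol tests.  Decimation keeps the Nyquist
# frequency above the 13 Hz upper alpha edge so the injected effect
# survives downsampling.
MICRO = ReducedProfile(
    n_subjects=2, n_trials_per_subject=6, decimate=9,
    layer_units=(8, 4), batch_size=20, max_epochs=3, k_folds=4,
)
SMALL = ReducedProfile(
    n_subjects=3, n_trials_per_subject=8, decimate=9,
    layer_units=(16, 8), batch_size=10, max_epochs=6, k_folds=4,
)


class TestMakeFolds:
    def test_195_trials_4_folds(self):
        folds = make_folds(195, 4, seed=0)
        assert sorted(folds.sizes(), reverse=True) == [49, 49, 49, 48]
        train_sizes = sorted(len(folds.fold_indices(f)[0]) for f in range(4))
        assert train_sizes == [146, 146, 146, 147]

    def test_singleton_folds(self):
        folds = make_folds(4, 4, seed=1)
        assert folds.sizes() == [1, 1, 1, 1]

    def test_too_few_trials(self):
        with pytest.raises(ExperimentError):
            make_folds(3, 4)

    def test_stratified_balances_classes(self):
        labels = np.array([0] * 8 + [1] * 4)
        folds = make_folds(12, 4, seed=0, labels=labels)
        for f in range(4):
            _, val = folds.fold_indices(f)
            assert (labels[val] == 0).sum() == 2
            assert (labels[val] == 1).sum() == 1

    @settings(deadline=None, derandomize=True)
    @given(st.integers(4, 120), st.integers(2, 6), st.integers(0, 5))
    def test_partition_property(self, n, k, seed):
        """Folds are disjoint, exhaustive, and near-equal for any n >= k."""
        folds = make_folds(max(n, k), k, seed=seed)
        n = max(n, k)
        all_val = np.concatenate([folds.fold_indices(f)[1] for f in range(k)])
        assert sorted(all_val) == list(range(n))
        sizes = folds.sizes()
        assert max(sizes) - min(sizes) <= 1
        for f in range(k):
            train, val = folds.fold_indices(f)
            assert not set(train) & set(val)
            assert len(train) + len(val) == n


class TestSelectEpoch:
    @pytest.mark.parametrize(
        "ts,expected", [((10, 12, 9, 11), 12), ((30, 30, 30, 30), 30), ((7,), 7)]
    )
    def test_max(self, ts, expected):
        assert select_epoch(ts) == expected

    def test_empty(self):
        with pytest.raises(ExperimentError):
            select_epoch([])


class _StubModel:
    """Fakes the model interface with a scripted validation-loss curve."""

    def __init__(self, val_losses):
        self.val_losses = list(val_losses)
        self.epoch = 0

    def train_epoch(self, x, y, batch_size, optimizer, rng):
        return 0.5

    def evaluate(self, x, y):
        loss = self.val_losses[self.epoch]
        self.epoch += 1
        return loss, 0.5


def _splits():
    x = np.zeros((4, 5, 1))
    y = np.tile([1.0, 0.0], (4, 1))
    return (x, y), (x, y)


class TestEarlyStopping:
    def test_patience_2_hand_trace(self):
        """Losses (1.0, 0.9, 0.91, 0.92): epochs 3 and 4 fail to improve
        on the 0.9 best, so training stops after epoch 4."""
        model = _StubModel([1.0, 0.9, 0.91, 0.92, 0.8])
        cfg = TrainConfig(max_epochs=10, patience=2)
        train, val = _splits()
        history, t = train_with_early_stopping(
            model, train, val, cfg, np.random.default_rng(0)
        )
        assert t == 4
        assert [h.val_loss for h in history] == [1.0, 0.9, 0.91, 0.92]

    def test_monotone_decrease_runs_to_max_epochs(self):
        model = _StubModel([1.0 - 0.05 * i for i in range(20)])
        cfg = TrainConfig(max_epochs=7, patience=2)
        train, val = _splits()
        _, t = train_with_early_stopping(model, train, val, cfg, np.random.default_rng(0))
        assert t == 7

    def test_min_delta_counts_equal_loss_as_no_improvement(self):
        model = _StubModel([1.0, 1.0, 1.0, 0.5])
        cfg = TrainConfig(max_epochs=10, patience=2, min_delta=0.0)
        train, val = _splits()
        _, t = train_with_early_stopping(model, train, val, cfg, np.random.default_rng(0))
        assert t == 3

    def test_empty_split_is_an_error(self):
        cfg = TrainConfig(max_epochs=2)
        empty = (np.zeros((0, 5, 1)), np.zeros((0, 2)))
        with pytest.raises(ExperimentError):
            train_with_early_stopping(
                _StubModel([1.0]), empty, _splits()[1], cfg, np.random.default_rng(0)
            )


class TestMajorityVote:
    def test_unanimous(self):
        preds = np.array([0] * 20 + [1] * 20)
        tids = ["a"] * 20 + ["b"] * 20
        assert trial_majority_vote(preds, tids) == {"a": 0, "b": 1}

    def test_11_vs_9_split(self):
        preds = np.array([1] * 11 + [0] * 9)
        assert trial_majority_vote(preds, ["t"] * 20) == {"t": 1}

    def test_tie_breaks_positive(self):
        preds = np.array([0] * 10 + [1] * 10)
        assert trial_majority_vote(preds, ["t"] * 20) == {"t": 0}

    def test_missing_segments_error(self):
        with pytest.raises(ExperimentError, match="19"):
            trial_majority_vote(np.zeros(19), ["t"] * 19)


@pytest.fixture(scope="module")
def micro_cv() -> CVResult:
    return recovery_cv(1.0, seed=0, profile=MICRO, architecture="lstm")


class TestRunCV:
    def test_mean_is_arithmetic_mean_of_folds(self, micro_cv):
        assert micro_cv.mean_accuracy == pytest.approx(
            np.mean(micro_cv.fold_accuracies)
        )
        assert micro_cv.mean_trial_accuracy == pytest.approx(
            np.mean(micro_cv.trial_accuracies)
        )

    def test_selected_epoch_is_max_of_fold_epochs(self, micro_cv):
        assert micro_cv.selected_epoch == max(micro_cv.early_stop_epochs)
        assert len(micro_cv.early_stop_epochs) == 4
        assert all(t <= MICRO.max_epochs for t in micro_cv.early_stop_epochs)

    def test_histories_align_with_stop_epochs(self, micro_cv):
        for history, t in zip(micro_cv.fold_histories, micro_cv.early_stop_epochs):
            assert len(history) == t

    def test_single_class_dataset_rejected(self):
        ds = make_recovery_dataset(1.0, seed=0, profile=MICRO)
        from rteeg.dataset import SegmentedDataset

        pos_only = np.flatnonzero(ds.labels[:, 0] == 1)
        sub = SegmentedDataset(
            data=ds.data[pos_only],
            labels=ds.labels[pos_only],
            trial_ids=[ds.trial_ids[i] for i in pos_only],
            montage=ds.montage,
            fs=ds.fs,
        )
        spec = ModelSpec(architecture="lstm", layer_units=(4,))
        with pytest.raises(ExperimentError, match="both classes"):
            run_cv(sub, spec, TrainConfig(max_epochs=1))


def _canned_result(acc, loss, epoch) -> CVResult:
    return CVResult(
        fold_accuracies=[acc] * 4,
        early_stop_epochs=[epoch] * 4,
        selected_epoch=epoch,
        mean_accuracy=acc,
        fold_histories=[[]] * 4,
        early_stop_accuracies=[acc] * 4,
        fold_val_losses=[loss] * 4,
        trial_accuracies=[acc] * 4,
        mean_trial_accuracy=acc,
        seed=0,
    )


class TestRunGrid:
    @pytest.fixture()
    def tiny_ds(self):
        return make_recovery_dataset(1.0, seed=0, profile=MICRO)

    def test_grid_cardinality_and_flags(self, tiny_ds, monkeypatch):
        canned = {
            ("sgd", 0.01): _canned_result(0.9, 0.4, 12),
            ("sgd", 0.001): _canned_result(1.0, 0.3, 3),   # perfect in 3 epochs
            ("sgd", 0.0001): _canned_result(0.6, 1.2, 8),  # val loss > 1
            ("rmsprop", 0.01): _canned_result(0.8, 0.5, 9),
            ("rmsprop", 0.001): _canned_result(0.8, 0.5, 9),
            ("rmsprop", 0.0001): _canned_result(0.8, 0.5, 9),
            ("adam", 0.01): _canned_result(0.8, 0.5, 9),
            ("adam", 0.001): _canned_result(1.0, 0.2, 30),  # perfect but slow: kept
            ("adam", 0.0001): _canned_result(0.8, 0.5, 9),
        }

        def fake_run_cv(dataset, spec, cfg, dtype=np.float32):
            return canned[(cfg.optimizer, cfg.learning_rate)]

        monkeypatch.setattr(experiment, "run_cv", fake_run_cv)
        spec = ModelSpec(architecture="bilstm", layer_units=(4,))
        grid = run_grid(tiny_ds, [spec], TrainConfig(max_epochs=30))
        assert len(grid.cells) == 9

        by_key = {(c.optimizer, c.learning_rate): c for c in grid.cells}
        assert by_key[("sgd", 0.001)].overfit  # 100% within <= 5 epochs
        assert by_key[("sgd", 0.001)].mean_accuracy is None
        assert by_key[("sgd", 0.0001)].overfit  # final val loss > 1
        assert not by_key[("sgd", 0.01)].overfit
        assert not by_key[("adam", 0.001)].overfit  # 100% but many epochs

        rows = grid.to_rows()
        assert len(rows) == 9
        flagged = [r for r in rows if r["accuracy"] == "-"]
        assert len(flagged) == 2
        assert rows[0]["channels"].split(", ") == list(tiny_ds.montage)


class TestStatisticalCalibration:
    def test_null_effect_no_excess_over_baseline(self):
        """Pooled over 6 seeds at delta=0, segment accuracy shows no
        significant one-sided excess over the majority baseline."""
        from scipy.stats import binomtest

        correct = 0
        total = 0
        for seed in range(10):
            r = recovery_cv(0.0, seed=seed, profile=MICRO, architecture="lstm")
            ds_trials = MICRO.n_subjects * MICRO.n_trials_per_subject
            n_val = ds_trials * 20
            correct += int(round(r.mean_accuracy * n_val))
            total += n_val
        p = binomtest(correct, total, 0.5, alternative="greater").pvalue
        assert p > 0.01

    def test_accuracy_monotone_in_effect_size(self):
        """Mean accuracy is non-decreasing over delta in {0, 0.5, 1.0, 1.5}
        at a fixed seed, allowing one inversion within 2 points."""
        accs = [
            recovery_cv(d, seed=3, profile=SMALL, architecture="lstm").mean_accuracy
            for d in (0.0, 0.5, 1.0, 1.5)
        ]
        inversions = [
            max(0.0, accs[i] - accs[i + 1]) for i in range(len(accs) - 1)
        ]
        bad = [v for v in inversions if v > 1e-12]
        assert len(bad) <= 1
        assert all(v <= 0.02 for v in bad), accs
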