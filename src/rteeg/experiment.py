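"""Training protocol.

The evaluation protocol is fourfold cross-validation at the *trial*
level: the labeled trials are randomly partitioned into four near-equal
subsets; each rotation trains on three and validates on one, so all
twenty 3-s segments of a trial share a fold and no segment of a
validation trial is ever seen in training.  Training instances are single
segments (timesteps x channels) inheriting their trial's label.

Epoch selection is two-phase.  Phase 1 trains each fold with early
stopping on validation loss (stop after ``patience`` consecutive epochs
without improvement, ``min_delta = 0``, no weight restoration), giving
per-fold stop epochs T1..T4.  The selected epoch is max(T1..T4).  Phase 2
retrains each fold from scratch for exactly that many epochs; the
reported accuracy is the mean of the phase-2 fold validation accuracies.
Segment-level accuracy is primary; trial-level majority-vote accuracy is
also recorded.

``run_grid`` sweeps optimizer x learning-rate cells and flags a cell as
overfit/non-convergent ("-") when its final validation loss exceeds 1 or
it reaches 100% validation accuracy within very few epochs; flagged
cells report no accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import signal as _signal

from .dataset import SegmentedDataset
from .models import ModelSpec, build_model
from .nn import make_optimizer

__all__ = [
    "TrainConfig",
    "FoldAssignment",
    "CVResult",
    "GridCell",
    "GridResult",
    "make_folds",
    "train_with_early_stopping",
    "select_epoch",
    "run_cv",
    "run_grid",
    "trial_majority_vote",
    "decimate_dataset",
]

OPTIMIZERS = ("sgd", "rmsprop", "adam")
LEARNING_RATES = (0.01, 0.001, 0.0001)


class ExperimentError(ValueError):
    pass


@dataclass(frozen=True)
class TrainConfig:
    """Training protocol parameters.

    ``standardize`` applies per-channel z-scoring using training-fold
    statistics before the model input.  ``overfit_epoch_limit`` is the
    "very few epochs" bound of the overfit flag.  All randomness (fold
    shuffle, weight init, dropout, batch order) derives from ``seed``.
    """

    optimizer: str = "sgd"
    learning_rate: float = 0.001
    batch_size: int = 10
    max_epochs: int = 50
    patience: int = 2
    min_delta: float = 0.0
    k_folds: int = 4
    standardize: bool = True
    stratified_folds: bool = False
    overfit_epoch_limit: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.batch_size <= 0 or self.max_epochs <= 0:
            raise ExperimentError("learning_rate, batch_size, max_epochs must be positive")
        if self.optimizer not in OPTIMIZERS:
            raise ExperimentError(f"optimizer must be one of {OPTIMIZERS}")


@dataclass(frozen=True)
class FoldAssignment:
    """Trial-level fold membership: ``membership[i]`` is the fold of
    trial ``i``.  Folds are disjoint, exhaustive, sizes differ by <= 1."""

    k: int
    membership: np.ndarray
    seed: int

    def fold_indices(self, fold: int) -> tuple[np.ndarray, np.ndarray]:
        """(train_idx, val_idx) for one rotation."""
        val = np.flatnonzero(self.membership == fold)
        train = np.flatnonzero(self.membership != fold)
        return train, val

    def sizes(self) -> list[int]:
        return [int((self.membership == f).sum()) for f in range(self.k)]


def make_folds(
    n_trials: int,
    k: int = 4,
    seed: int = 0,
    labels: np.ndarray | None = None,
) -> FoldAssignment:
    """Randomly partition trials into k near-equal folds.

    With ``labels`` (class index per trial) the split is stratified:
    each class is partitioned near-equally across folds.  Default is the
    plain unstratified random split.
    """
    if n_trials < k:
        raise ExperimentError(f"cannot split {n_trials} trials into {k} folds")
    rng = np.random.default_rng(seed)
    membership = np.empty(n_trials, dtype=int)
    if labels is None:
        order = rng.permutation(n_trials)
        for pos, trial in enumerate(order):
            membership[trial] = pos % k
    else:
        labels = np.asarray(labels)
        for cls in np.unique(labels):
            idx = np.flatnonzero(labels == cls)
            idx = rng.permutation(idx)
            for pos, trial in enumerate(idx):
                membership[trial] = pos % k
    return FoldAssignment(k=k, membership=membership, seed=seed)


@dataclass
class EpochRecord:
    train_loss: float
    val_loss: float
    val_accuracy: float


def train_with_early_stopping(
    model,
    train_data: tuple[np.ndarray, np.ndarray],
    val_data: tuple[np.ndarray, np.ndarray],
    cfg: TrainConfig,
    rng: np.random.Generator,
) -> tuple[list[EpochRecord], int]:
    """Train with validation-loss early stopping.

    Stops once the validation loss has failed to improve (by more than
    ``min_delta``) for ``patience`` consecutive epochs, or at
    ``max_epochs``.  Weights are not restored to the best epoch.  Returns
    (per-epoch history, T) where T is the number of epochs actually run.

    ``model`` needs ``train_epoch(x, y, batch_size, optimizer, rng)`` and
    ``evaluate(x, y) -> (loss, accuracy)``.
    """
    x_train, y_train = train_data
    x_val, y_val = val_data
    if len(x_train) == 0 or len(x_val) == 0:
        raise ExperimentError("training and validation splits must be non-empty")
    optimizer = make_optimizer(cfg.optimizer, cfg.learning_rate)
    best = np.inf
    bad_epochs = 0
    history: list[EpochRecord] = []
    for _ in range(cfg.max_epochs):
        train_loss = model.train_epoch(x_train, y_train, cfg.batch_size, optimizer, rng)
        val_loss, val_acc = model.evaluate(x_val, y_val)
        history.append(EpochRecord(train_loss, val_loss, val_acc))
        if val_loss < best - cfg.min_delta:
            best = val_loss
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= cfg.patience:
                break
    return history, len(history)


def select_epoch(ts: Sequence[int]) -> int:
    """The fixed retraining epoch: the maximum of the per-fold stop epochs."""
    if len(ts) == 0:
        raise ExperimentError("no early-stopping epochs to select from")
    return int(max(ts))


def trial_majority_vote(
    predictions: np.ndarray,
    trial_ids: Sequence[str],
    n_segments: int = 20,
) -> dict[str, int]:
    """Reduce segment-level class predictions to one class per trial by
    majority vote; ties break toward class 0 (positive).  Every trial
    must contribute exactly ``n_segments`` predictions."""
    predictions = np.asarray(predictions)
    if len(predictions) != len(trial_ids):
        raise ExperimentError("predictions and trial_ids must align")
    votes: dict[str, list[int]] = {}
    for pred, tid in zip(predictions, trial_ids):
        votes.setdefault(tid, []).append(int(pred))
    out = {}
    for tid, v in votes.items():
        if len(v) != n_segments:
            raise ExperimentError(
                f"trial {tid} has {len(v)} segment predictions, expected {n_segments}"
            )
        n_neg = sum(v)
        out[tid] = 1 if n_neg > len(v) / 2 else 0
    return out


@dataclass
class CVResult:
    """Machine-readable outcome of one cross-validated configuration."""

    fold_accuracies: list[float]  # phase-2 segment-level val accuracy
    early_stop_epochs: list[int]  # T1..Tk
    selected_epoch: int
    mean_accuracy: float
    fold_histories: list[list[EpochRecord]]  # phase 1
    early_stop_accuracies: list[float]  # phase-1 accuracy at stop
    fold_val_losses: list[float]  # phase-2 final val loss
    trial_accuracies: list[float]  # phase-2 majority-vote accuracy
    mean_trial_accuracy: float
    seed: int

    @property
    def mean_early_stop_accuracy(self) -> float:
        return float(np.mean(self.early_stop_accuracies))


def _segment_instances(ds: SegmentedDataset):
    """Flatten trials x segments into per-segment instances."""
    n_trials, n_seg, n_t, n_ch = ds.data.shape
    x = ds.data.reshape(n_trials * n_seg, n_t, n_ch)
    y = np.repeat(ds.labels, n_seg, axis=0)
    seg_trial = np.repeat(np.arange(n_trials), n_seg)
    return x, y, seg_trial


def _standardize(x_train, x_val):
    mean = x_train.mean(axis=(0, 1), keepdims=True)
    sd = x_train.std(axis=(0, 1), keepdims=True)
    sd[sd < 1e-12] = 1.0
    return (x_train - mean) / sd, (x_val - mean) / sd


def decimate_dataset(ds: SegmentedDataset, q: int) -> SegmentedDataset:
    """Anti-aliased downsampling of the timestep axis by integer factor q
    (scipy.signal.decimate).  Used by reduced training profiles; the
    segment count and labels are untouched."""
    if q <= 1:
        return ds
    data = _signal.decimate(ds.data, q, axis=2, zero_phase=True)
    return SegmentedDataset(
        data=np.ascontiguousarray(data),
        labels=ds.labels,
        trial_ids=ds.trial_ids,
        montage=ds.montage,
        fs=ds.fs / q,
    )


def run_cv(
    dataset: SegmentedDataset,
    spec: ModelSpec,
    cfg: TrainConfig,
    dtype=np.float32,
) -> CVResult:
    """Cross-validate one model configuration on a segmented dataset.

    Implements the two-phase protocol described in the module docstring.
    Deterministic given ``cfg.seed``: fold shuffle, per-fold weight
    initialization, dropout and batch order all derive from it.
    """
    n_pos, n_neg = dataset.class_counts()
    if n_pos == 0 or n_neg == 0:
        raise ExperimentError("dataset must contain both classes")
    n_trials = dataset.n_trials
    if spec.input_timesteps != dataset.data.shape[2]:
        spec = replace(spec, input_timesteps=dataset.data.shape[2])
    if spec.input_channels != dataset.data.shape[3]:
        spec = replace(spec, input_channels=dataset.data.shape[3])

    x_all, y_all, seg_trial = _segment_instances(dataset)
    x_all = x_all.astype(dtype)
    y_all = y_all.astype(dtype)
    trial_labels = np.argmax(dataset.labels, axis=1)

    master = np.random.SeedSequence(cfg.seed)
    fold_seed, *children = master.spawn(1 + 2 * cfg.k_folds)
    folds = make_folds(
        n_trials,
        cfg.k_folds,
        seed=fold_seed.generate_state(1)[0] % (2**31),
        labels=trial_labels if cfg.stratified_folds else None,
    )

    def fold_arrays(fold: int):
        train_t, val_t = folds.fold_indices(fold)
        # leakage guard: a trial never appears on both sides
        assert not set(train_t) & set(val_t)
        train_mask = np.isin(seg_trial, train_t)
        val_mask = np.isin(seg_trial, val_t)
        x_tr, x_va = x_all[train_mask], x_all[val_mask]
        if cfg.standardize:
            x_tr, x_va = _standardize(x_tr, x_va)
        return (
            (x_tr.astype(dtype), y_all[train_mask]),
            (x_va.astype(dtype), y_all[val_mask]),
            seg_trial[val_mask],
            val_t,
        )

    # phase 1: early-stopped runs give T1..Tk
    histories, ts, stop_accs = [], [], []
    for fold in range(cfg.k_folds):
        train_data, val_data, _, _ = fold_arrays(fold)
        rng = np.random.default_rng(children[fold])
        model = build_model(spec, rng=rng, dtype=dtype)
        history, t = train_with_early_stopping(model, train_data, val_data, cfg, rng)
        histories.append(history)
        ts.append(t)
        stop_accs.append(history[-1].val_accuracy)
    selected = select_epoch(ts)

    # phase 2: retrain from scratch at the fixed selected epoch
    accs, losses, trial_accs = [], [], []
    fixed_cfg = replace(cfg, max_epochs=selected, patience=selected + 1)
    for fold in range(cfg.k_folds):
        train_data, val_data, val_seg_trial, val_t = fold_arrays(fold)
        rng = np.random.default_rng(children[cfg.k_folds + fold])
        model = build_model(spec, rng=rng, dtype=dtype)
        history, _ = train_with_early_stopping(model, train_data, val_data, fixed_cfg, rng)
        losses.append(history[-1].val_loss)
        accs.append(history[-1].val_accuracy)

        preds = model.predict(val_data[0])
        tid_of = {i: dataset.trial_ids[i] for i in val_t}
        voted = trial_majority_vote(
            preds,
            [tid_of[i] for i in val_seg_trial],
            n_segments=dataset.data.shape[1],
        )
        true_of = {dataset.trial_ids[i]: trial_labels[i] for i in val_t}
        correct = sum(voted[tid] == true_of[tid] for tid in voted)
        trial_accs.append(correct / len(voted))

    return CVResult(
        fold_accuracies=accs,
        early_stop_epochs=ts,
        selected_epoch=selected,
        mean_accuracy=float(np.mean(accs)),
        fold_histories=histories,
        early_stop_accuracies=stop_accs,
        fold_val_losses=losses,
        trial_accuracies=trial_accs,
        mean_trial_accuracy=float(np.mean(trial_accs)),
        seed=cfg.seed,
    )


@dataclass
class GridCell:
    dataset: str
    montage: tuple[str, ...]
    architecture: str
    optimizer: str
    learning_rate: float
    mean_accuracy: float | None
    epoch: int
    overfit: bool
    result: CVResult = field(repr=False)


@dataclass
class GridResult:
    cells: list[GridCell]

    def to_rows(self) -> list[dict]:
        return [
            {
                "dataset": c.dataset,
                "channels": ", ".join(c.montage),
                "model": c.architecture,
                "optimizer": c.optimizer,
                "learning_rate": c.learning_rate,
                "accuracy": "-" if c.overfit else f"{100 * c.mean_accuracy:.1f}%",
                "epoch": c.epoch,
            }
            for c in self.cells
        ]


def run_grid(
    dataset: SegmentedDataset,
    specs: Sequence[ModelSpec],
    cfg: TrainConfig,
    optimizers: Sequence[str] = OPTIMIZERS,
    learning_rates: Sequence[float] = LEARNING_RATES,
    dataset_name: str = "1",
) -> GridResult:
    """Sweep architecture x optimizer x learning-rate cells, one
    cross-validated run per cell, flagging overfit/non-convergent cells.

    A cell is flagged ("-") when its mean final validation loss exceeds 1
    or it reaches 100% validation accuracy within
    ``cfg.overfit_epoch_limit`` epochs; flagged cells carry no accuracy.
    """
    cells = []
    for spec in specs:
        for opt in optimizers:
            for lr in learning_rates:
                cell_cfg = replace(cfg, optimizer=opt, learning_rate=lr)
                result = run_cv(dataset, spec, cell_cfg)
                mean_loss = float(np.mean(result.fold_val_losses))
                overfit = mean_loss > 1.0 or (
                    result.mean_accuracy == 1.0
                    and result.selected_epoch <= cfg.overfit_epoch_limit
                )
                cells.append(
                    GridCell(
                        dataset=dataset_name,
                        montage=dataset.montage,
                        architecture=spec.architecture,
                        optimizer=opt,
                        learning_rate=lr,
                        mean_accuracy=None if overfit else result.mean_accuracy,
                        epoch=result.selected_epoch,
                        overfit=overfit,
                        result=result,
                    )
                )
    return GridResult(cells=cells)
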