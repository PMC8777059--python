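"""Dataset assembly.

Preprocessed, labeled trials are assembled into a 4-D tensor of
trials x segments x timesteps x channels plus a trials x 2 one-hot label
matrix.  Each 60-s trial is cut into 20 contiguous non-overlapping 3-s
segments (750 samples at 250 Hz); excluded trials are dropped before
assembly, mirroring the study's 396 -> 195 reduction.  Channel-subset
datasets select the 4-channel eyewear (F7, F8, T7, T8) or headband
(F3, F4, F7, F8) montages from the full 8-channel one, preserving
canonical order.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np

from .io import DEFAULT_MONTAGE, RawRecording
from .labeling import EmotionLabel

__all__ = [
    "MONTAGE_SUBSETS",
    "SegmentedDataset",
    "segment_trial",
    "one_hot",
    "assemble_dataset",
    "save_dataset",
    "load_dataset",
]

N_SEGMENTS = 20
SEGMENT_SECONDS = 3.0

# named montages; subsets keep the canonical channel order
MONTAGE_SUBSETS: dict[str, tuple[str, ...]] = {
    "full": DEFAULT_MONTAGE,
    "eyewear": ("F7", "F8", "T7", "T8"),
    "headband": ("F3", "F4", "F7", "F8"),
}

# one-hot column order: column 0 = positive, column 1 = negative
LABEL_COLUMNS = (EmotionLabel.POSITIVE, EmotionLabel.NEGATIVE)


class DatasetError(ValueError):
    pass


@dataclass
class SegmentedDataset:
    """Trials x segments x timesteps x channels tensor with one-hot labels.

    ``trial_ids`` carry provenance (e.g. ``"s03/17"``) and align row-wise
    with ``data`` and ``labels``.
    """

    data: np.ndarray
    labels: np.ndarray
    trial_ids: list[str]
    montage: tuple[str, ...]
    fs: float

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise DatasetError("data must be 4-D (trials, segments, timesteps, channels)")
        if self.labels.shape != (self.data.shape[0], 2):
            raise DatasetError("labels must be (n_trials, 2)")
        if len(self.trial_ids) != self.data.shape[0]:
            raise DatasetError("trial_ids must align with data rows")
        if self.data.shape[3] != len(self.montage):
            raise DatasetError("channel axis must match montage length")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.data.shape

    def class_counts(self) -> tuple[int, int]:
        """(n_positive, n_negative) trials."""
        return int(self.labels[:, 0].sum()), int(self.labels[:, 1].sum())


def segment_trial(
    trial: np.ndarray, fs: float, n_segments: int = N_SEGMENTS,
    segment_seconds: float = SEGMENT_SECONDS,
) -> np.ndarray:
    """Cut a channels x samples trial into contiguous non-overlapping
    segments, returning segments x timesteps x channels.

    The trial length must equal ``n_segments * segment_seconds * fs``
    exactly; concatenating the segments reconstructs the trial bit for
    bit.  No silent truncation or padding.
    """
    trial = np.asarray(trial)
    if trial.ndim != 2:
        raise DatasetError("trial must be channels x samples")
    seg_len = int(round(segment_seconds * fs))
    expected = n_segments * seg_len
    if trial.shape[1] != expected:
        raise DatasetError(
            f"trial has {trial.shape[1]} samples; need exactly {expected} "
            f"({n_segments} x {seg_len})"
        )
    n_ch = trial.shape[0]
    # (channels, segments, timesteps) -> (segments, timesteps, channels)
    return trial.reshape(n_ch, n_segments, seg_len).transpose(1, 2, 0)


def one_hot(labels: list[EmotionLabel]) -> np.ndarray:
    """Encode positive/negative labels as rows of a trials x 2 matrix
    (column 0 = positive).  Excluded labels are an error here."""
    out = np.zeros((len(labels), 2), dtype=float)
    for i, label in enumerate(labels):
        if label not in LABEL_COLUMNS:
            raise DatasetError(
                f"label {label} cannot be one-hot encoded; drop excluded "
                "trials before assembly"
            )
        out[i, LABEL_COLUMNS.index(label)] = 1.0
    return out


def assemble_dataset(
    trials: list[tuple[str, RawRecording, EmotionLabel]],
    subset: str = "full",
) -> SegmentedDataset:
    """Assemble (trial_id, preprocessed recording, label) triples into a
    segmented dataset on the named channel subset.

    Every recording must carry the full canonical montage and exactly
    ``20 x 3 s x fs`` samples; labels must be positive or negative.
    """
    if subset not in MONTAGE_SUBSETS:
        raise DatasetError(f"unknown montage subset {subset!r}")
    montage = MONTAGE_SUBSETS[subset]

    fs = trials[0][1].fs if trials else 250.0
    seg_len = int(round(SEGMENT_SECONDS * fs))
    tensors, labels, ids = [], [], []
    for trial_id, rec, label in trials:
        if label not in LABEL_COLUMNS:
            raise DatasetError(f"trial {trial_id}: excluded label reached assembly")
        missing = [c for c in montage if c not in rec.montage]
        if missing:
            raise DatasetError(f"trial {trial_id}: montage lacks channels {missing}")
        if rec.fs != fs:
            raise DatasetError(f"trial {trial_id}: sampling rate mismatch")
        chan_idx = [rec.montage.index(c) for c in montage]
        try:
            segs = segment_trial(rec.samples[chan_idx], rec.fs)
        except DatasetError as exc:
            raise DatasetError(f"trial {trial_id}: {exc}") from exc
        tensors.append(segs)
        labels.append(label)
        ids.append(trial_id)

    if tensors:
        data = np.stack(tensors)
        label_matrix = one_hot(labels)
    else:
        data = np.zeros((0, N_SEGMENTS, seg_len, len(montage)))
        label_matrix = np.zeros((0, 2))
    return SegmentedDataset(
        data=data, labels=label_matrix, trial_ids=ids, montage=montage, fs=fs
    )


def save_dataset(ds: SegmentedDataset, path: str | Path) -> None:
    """Persist to a single HDF5 file with datasets ``data``, ``labels``,
    ``trial_ids`` and attributes ``montage``, ``fs``."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=ds.data)
        f.create_dataset("labels", data=ds.labels)
        f.create_dataset(
            "trial_ids", data=np.array(ds.trial_ids, dtype=h5py.string_dtype())
        )
        f.attrs["montage"] = list(ds.montage)
        f.attrs["fs"] = ds.fs


def load_dataset(path: str | Path) -> SegmentedDataset:
    with h5py.File(path, "r") as f:
        return SegmentedDataset(
            data=f["data"][()],
            labels=f["labels"][()],
            trial_ids=[s.decode() for s in f["trial_ids"][()]],
            montage=tuple(f.attrs["montage"]),
            fs=float(f.attrs["fs"]),
        )
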