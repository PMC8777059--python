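"""File formats for the acquisition pipeline.

Recordings travel as OpenBCI-GUI-dialect TXT (the format the acquisition
GUI streams to disk) and are converted to plain CSV for processing; trial
self-assessments travel as a small ratings CSV.  All numeric fields
round-trip losslessly: the TXT/CSV writers emit shortest-repr floats, so
``read(write(x))`` reproduces ``x`` bit for bit.

OpenBCI TXT dialect (declared fixture convention, tolerant of GUI-version
drift): header lines prefixed with ``%`` holding ``key = value`` metadata,
then comma-separated data rows of ``sample_index, ch1..chN[, extra...]``;
extra trailing columns are ignored with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .labeling import Ratings

__all__ = [
    "RawRecording",
    "RatingsRow",
    "RatingsTable",
    "read_openbci_txt",
    "write_openbci_txt",
    "write_csv",
    "read_csv",
    "read_ratings_csv",
    "write_ratings_csv",
]

DEFAULT_MONTAGE = ("F3", "F4", "F7", "F8", "T7", "T8", "P3", "P4")


class FormatError(ValueError):
    """Malformed acquisition or ratings file."""


@dataclass
class RawRecording:
    """One trial's multichannel EEG in microvolts.

    ``samples`` is channels x timepoints; ``sample_index`` is the
    per-row acquisition counter the Cyton board emits (wraps at 256).
    """

    samples: np.ndarray
    fs: float
    montage: tuple[str, ...]
    sample_index: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a channels x timepoints matrix")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if len(self.montage) != self.samples.shape[0]:
            raise ValueError(
                f"montage has {len(self.montage)} names for "
                f"{self.samples.shape[0]} channels"
            )
        if len(set(self.montage)) != len(self.montage):
            raise ValueError("montage names must be unique")
        self.montage = tuple(self.montage)

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass(frozen=True)
class RatingsRow:
    subject_id: str
    trial_index: int
    pleasure: int
    arousal: int
    stress: int


class RatingsTable:
    """Validated per-trial self-assessments keyed by (subject, trial)."""

    def __init__(self, rows: Iterable[RatingsRow]):
        self.rows: list[RatingsRow] = list(rows)
        seen: set[tuple[str, int]] = set()
        for row in self.rows:
            Ratings(row.pleasure, row.arousal, row.stress)  # range check
            key = (row.subject_id, row.trial_index)
            if key in seen:
                raise FormatError(f"duplicate (subject, trial) key {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    def ratings(self) -> list[Ratings]:
        return [Ratings(r.pleasure, r.arousal, r.stress) for r in self.rows]

    def get(self, subject_id: str, trial_index: int) -> Ratings:
        for r in self.rows:
            if r.subject_id == subject_id and r.trial_index == trial_index:
                return Ratings(r.pleasure, r.arousal, r.stress)
        raise KeyError((subject_id, trial_index))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (r.subject_id, r.trial_index, r.pleasure, r.arousal, r.stress)
                for r in self.rows
            ],
            columns=["subject_id", "trial_index", "pleasure", "arousal", "stress"],
        )


def _format_float(x: float) -> str:
    # repr of a Python float is the shortest string that round-trips
    return repr(float(x))


def write_openbci_txt(rec: RawRecording, path: str | Path) -> None:
    """Write a recording in the OpenBCI-GUI TXT dialect."""
    path = Path(path)
    idx = rec.sample_index
    if idx is None:
        idx = np.arange(rec.n_samples) % 256
    lines = [
        "%OpenBCI Raw EEG Data",
        f"%Number of channels = {rec.n_channels}",
        f"%Sample Rate = {rec.fs:g} Hz",
        f"%Channels = {','.join(rec.montage)}",
    ]
    for key, value in rec.meta.items():
        if key not in {"Number of channels", "Sample Rate", "Channels"}:
            lines.append(f"%{key} = {value}")
    cols = rec.samples.T  # timepoints x channels
    for i in range(rec.n_samples):
        row = [str(int(idx[i]))] + [_format_float(v) for v in cols[i]]
        lines.append(",".join(row))
    try:
        path.write_text("\n".join(lines) + "\n")
    except OSError as exc:
        raise OSError(f"failed to write recording to {path}: {exc}") from exc


def read_openbci_txt(
    path: str | Path,
    fs: float | None = None,
    montage: Sequence[str] | None = None,
) -> RawRecording:
    """Parse an OpenBCI-GUI TXT export.

    Header ``%`` lines become ``meta``; the sampling rate is taken from a
    ``Sample Rate`` header unless overridden by ``fs``.  Data rows are
    ``sample_index, ch1..chN``; trailing extra columns (aux channels,
    timestamps) are dropped with a warning.  Malformed rows raise
    :class:`FormatError` naming the line; no row is silently skipped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta: dict[str, str] = {}
    data_rows: list[list[float]] = []
    indices: list[int] = []
    n_channels: int | None = None
    extra_warned = False
    with open(path) as fh:
        for lineno, raw_line in enumerate(fh, start=1):
            line = raw_line.strip()
            if not line:
                continue
            if line.startswith("%"):
                body = line[1:].strip()
                if "=" in body:
                    key, _, value = body.partition("=")
                    meta[key.strip()] = value.strip()
                else:
                    meta.setdefault("comments", "")
                    meta["comments"] += body + "\n"
                continue
            parts = line.split(",")
            if n_channels is None:
                declared = meta.get("Number of channels")
                if declared is not None:
                    n_channels = int(declared)
                else:
                    n_channels = len(parts) - 1
                if len(parts) - 1 < n_channels:
                    raise FormatError(
                        f"{path}:{lineno}: expected {n_channels} channel "
                        f"values, found {len(parts) - 1}"
                    )
            if len(parts) - 1 < n_channels:
                raise FormatError(
                    f"{path}:{lineno}: expected {n_channels} channel values, "
                    f"found {len(parts) - 1}"
                )
            if len(parts) - 1 > n_channels and not extra_warned:
                warnings.warn(
                    f"{path}: ignoring {len(parts) - 1 - n_channels} extra "
                    "trailing column(s) beyond the EEG channels",
                    stacklevel=2,
                )
                extra_warned = True
            try:
                indices.append(int(float(parts[0])))
                data_rows.append([float(v) for v in parts[1 : 1 + n_channels]])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: malformed row: {exc}") from exc
    if not data_rows:
        raise FormatError(f"{path}: no data rows found")

    if fs is None:
        rate = meta.get("Sample Rate")
        if rate is None:
            raise FormatError(f"{path}: no Sample Rate header and no fs override")
        fs = float(rate.lower().replace("hz", "").strip())
    if montage is None:
        if "Channels" in meta:
            montage = tuple(name.strip() for name in meta["Channels"].split(","))
        else:
            montage = tuple(f"ch{i + 1}" for i in range(n_channels))
    samples = np.array(data_rows, dtype=float).T
    return RawRecording(
        samples=samples,
        fs=fs,
        montage=tuple(montage),
        sample_index=np.array(indices, dtype=int),
        meta=meta,
    )


def write_csv(rec: RawRecording, path: str | Path) -> None:
    """Write a recording as plain CSV: header row of channel names, one
    row per timepoint (shortest-repr floats, exact round-trip)."""
    path = Path(path)
    lines = [",".join(rec.montage)]
    cols = rec.samples.T
    for i in range(rec.n_samples):
        lines.append(",".join(_format_float(v) for v in cols[i]))
    try:
        path.write_text("\n".join(lines) + "\n")
    except OSError as exc:
        raise OSError(f"failed to write CSV to {path}: {exc}") from exc


def read_csv(path: str | Path, fs: float) -> RawRecording:
    """Read a recording previously written by :func:`write_csv`."""
    frame = pd.read_csv(path, float_precision="round_trip")
    return RawRecording(
        samples=frame.to_numpy(dtype=float).T,
        fs=fs,
        montage=tuple(frame.columns),
    )


RATINGS_COLUMNS = ["subject_id", "trial_index", "pleasure", "arousal", "stress"]


def write_ratings_csv(table: RatingsTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, index=False)


def read_ratings_csv(path: str | Path) -> RatingsTable:
    """Read and validate a ratings CSV.

    Every row is range-checked (pleasure/arousal integer in [-4, 4],
    stress integer in [1, 7]); an out-of-range value or duplicate
    (subject, trial) key raises :class:`FormatError` naming the row.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path)
    missing = [c for c in RATINGS_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    rows = []
    for i, rec in enumerate(frame.itertuples(index=False)):
        try:
            rows.append(
                RatingsRow(
                    subject_id=str(rec.subject_id),
                    trial_index=int(rec.trial_index),
                    pleasure=int(rec.pleasure),
                    arousal=int(rec.arousal),
                    stress=int(rec.stress),
                )
            )
            Ratings(rows[-1].pleasure, rows[-1].arousal, rows[-1].stress)
        except (ValueError, TypeError) as exc:
            raise FormatError(f"{path}: row {i + 2}: {exc}") from exc
    try:
        return RatingsTable(rows)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc
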