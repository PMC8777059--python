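"""Synthetic cohort generation.

The study's raw recordings are not publicly deposited, so the pipeline is
exercised on synthetic cohorts that emulate their statistical structure:
11 subjects x 36 one-minute conversation trials recorded on an 8-channel
dry-electrode montage at 250 Hz, with per-trial self-assessment ratings.

Each channel is a sum of
* 1/f-shaped broadband background activity,
* narrowband theta / alpha / beta oscillations (band-limited noise with
  calibrated RMS amplitudes),
* 60 Hz mains interference (Kansai grid), and
* slow (< 0.5 Hz) baseline drift.

The learnable class difference is a lateralized alpha-power effect: for
positive-emotion trials the log-ratio of alpha power on the left lateral
channels (F7, T7) versus the right (F8, T8) is shifted by +delta/2, for
negative trials by -delta/2, so the between-class log-ratio difference is
the configured ``effect_size`` delta.  Excluded trials carry a
half-strength effect of random sign.  ``effect_size = 0`` makes the
classes indistinguishable by construction.

Ratings are drawn uniformly from the rating-grid cells belonging to the
requested class (cells enumerated programmatically), so re-labeling a
generated rating always recovers the label it was generated from.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np

from .io import (
    DEFAULT_MONTAGE,
    RatingsRow,
    RatingsTable,
    RawRecording,
    write_openbci_txt,
    write_ratings_csv,
)
from .labeling import EmotionLabel, Ratings, label_ps, rating_grid

__all__ = [
    "GeneratorConfig",
    "Session",
    "SyntheticCohort",
    "generate_cohort",
    "generate_trial_eeg",
    "generate_ratings",
    "write_cohort",
    "BAND_EDGES",
]

# canonical EEG band edges in Hz
BAND_EDGES: dict[str, tuple[float, float]] = {
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
}

LEFT_ALPHA_CHANNELS = ("F7", "T7")
RIGHT_ALPHA_CHANNELS = ("F8", "T8")

# paper composition: 126 positive / 69 negative / 201 excluded of 396
DEFAULT_LABEL_MIX = (126 / 396, 69 / 396, 201 / 396)

LABEL_ORDER = (EmotionLabel.POSITIVE, EmotionLabel.NEGATIVE, EmotionLabel.EXCLUDED)


class ConfigurationError(ValueError):
    """Invalid generator configuration."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Conditions of the emulated study.

    ``band_powers`` are RMS amplitudes in microvolts of the narrowband
    oscillations; ``background_rms`` scales the 1/f background;
    ``effect_size`` is the class-conditional left-right alpha log-power
    ratio difference (dimensionless, see module docstring);
    ``label_mix`` are target proportions of positive / negative /
    excluded trials; ``stratified`` fixes the class counts exactly
    (largest-remainder allocation) instead of sampling them.
    """

    n_subjects: int = 11
    n_trials_per_subject: int = 36
    fs: float = 250.0
    duration: float = 60.0
    montage: tuple[str, ...] = DEFAULT_MONTAGE
    band_powers: dict = field(
        default_factory=lambda: {"theta": 4.0, "alpha": 6.0, "beta": 2.5}
    )
    background_rms: float = 5.0
    background_exponent: float = 1.0
    line_freq: float = 60.0
    line_noise_amp: float = 2.0
    drift_amp: float = 20.0
    drift_cutoff: float = 0.3
    effect_size: float = 1.0
    alpha_jitter_sd: float = 0.05
    subject_amp_sd: float = 0.1
    label_mix: tuple[float, float, float] = DEFAULT_LABEL_MIX
    stratified: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects <= 0 or self.n_trials_per_subject <= 0:
            raise ConfigurationError("subject and trial counts must be positive")
        if self.fs <= 0 or self.duration <= 0:
            raise ConfigurationError("fs and duration must be positive")
        if len(set(self.montage)) != len(self.montage) or not self.montage:
            raise ConfigurationError("montage names must be non-empty and unique")
        if abs(sum(self.label_mix) - 1.0) > 1e-9 or any(p < 0 for p in self.label_mix):
            raise ConfigurationError("label_mix must be non-negative and sum to 1")
        if not 0 < self.drift_cutoff < 0.5:
            raise ConfigurationError("drift cutoff must lie in (0, 0.5) Hz")
        unknown = set(self.band_powers) - set(BAND_EDGES)
        if unknown:
            raise ConfigurationError(f"unknown bands {sorted(unknown)}")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration))

    @property
    def n_trials(self) -> int:
        return self.n_subjects * self.n_trials_per_subject


class Session(NamedTuple):
    subject_id: str
    trial_index: int
    recording: RawRecording
    ratings: Ratings
    true_label: EmotionLabel


@dataclass
class SyntheticCohort:
    sessions: list[Session]
    config: GeneratorConfig

    def __len__(self) -> int:
        return len(self.sessions)

    def ratings_table(self) -> RatingsTable:
        return RatingsTable(
            RatingsRow(
                s.subject_id, s.trial_index, s.ratings.pleasure,
                s.ratings.arousal, s.ratings.stress,
            )
            for s in self.sessions
        )


def _shaped_noise(
    rng: np.random.Generator,
    shape: tuple[int, int],
    fs: float,
    weight_fn,
    target_rms: float,
) -> np.ndarray:
    """Gaussian noise with the given one-sided spectral weighting,
    normalized per row to ``target_rms``."""
    n = shape[1]
    white = rng.standard_normal(shape)
    spectrum = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    w = weight_fn(freqs)
    w[0] = 0.0  # no DC
    shaped = np.fft.irfft(spectrum * w, n=n, axis=1)
    rms = np.sqrt(np.mean(shaped**2, axis=1, keepdims=True))
    rms[rms == 0] = 1.0
    return shaped / rms * target_rms


def _alpha_log_gains(
    label: EmotionLabel, config: GeneratorConfig, rng: np.random.Generator
) -> dict[str, float]:
    """Per-channel natural-log amplitude gain of the alpha oscillation."""
    delta = config.effect_size
    if label is EmotionLabel.POSITIVE:
        offset = +delta / 2
    elif label is EmotionLabel.NEGATIVE:
        offset = -delta / 2
    else:  # half-strength effect, random laterality
        offset = (delta / 4) * (1 if rng.random() < 0.5 else -1)
    gains: dict[str, float] = {}
    for name in config.montage:
        if name in LEFT_ALPHA_CHANNELS:
            g = +offset / 4
        elif name in RIGHT_ALPHA_CHANNELS:
            g = -offset / 4
        else:
            g = 0.0
        # small per-channel amplitude jitter, zero mean in log space
        gains[name] = g + rng.normal(0.0, config.alpha_jitter_sd)
    return gains


def generate_trial_eeg(
    label: EmotionLabel,
    config: GeneratorConfig,
    rng: np.random.Generator,
    subject_gain: float = 1.0,
) -> RawRecording:
    """Simulate one trial's multichannel EEG conditioned on its label.

    ``subject_gain`` is a per-subject overall amplitude factor (individual
    differences in signal amplitude; 1.0 when generating a lone trial).
    """
    if not isinstance(label, EmotionLabel):
        raise ConfigurationError(f"invalid label {label!r}")
    n = config.n_samples
    n_ch = len(config.montage)
    shape = (n_ch, n)
    fs = config.fs

    beta_exp = config.background_exponent
    background = _shaped_noise(
        rng, shape, fs,
        lambda f: np.where(f > 0, np.maximum(f, 1.0) ** (-beta_exp / 2.0), 0.0),
        config.background_rms,
    )

    signal = background
    log_gains = _alpha_log_gains(label, config, rng)
    for band, amp in config.band_powers.items():
        lo, hi = BAND_EDGES[band]
        osc = _shaped_noise(
            rng, shape, fs,
            lambda f, lo=lo, hi=hi: ((f >= lo) & (f < hi)).astype(float),
            amp,
        )
        if band == "alpha":
            gain = np.exp([log_gains[name] for name in config.montage])
            osc = osc * gain[:, None]
        signal = signal + osc

    if config.line_noise_amp > 0:
        t = np.arange(n) / fs
        phases = rng.uniform(0, 2 * np.pi, size=n_ch)
        signal = signal + config.line_noise_amp * np.sin(
            2 * np.pi * config.line_freq * t[None, :] + phases[:, None]
        )

    if config.drift_amp > 0:
        drift = _shaped_noise(
            rng, shape, fs,
            lambda f: ((f > 0) & (f <= config.drift_cutoff)).astype(float),
            config.drift_amp,
        )
        signal = signal + drift

    return RawRecording(
        samples=signal * subject_gain,
        fs=fs,
        montage=config.montage,
        meta={"synthetic": "true", "true_label_effect": f"{config.effect_size:g}"},
    )


_GRID_BY_LABEL: dict[EmotionLabel, list[Ratings]] | None = None


def _grid_by_label() -> dict[EmotionLabel, list[Ratings]]:
    global _GRID_BY_LABEL
    if _GRID_BY_LABEL is None:
        parts: dict[EmotionLabel, list[Ratings]] = {lbl: [] for lbl in EmotionLabel}
        for cell in rating_grid():
            parts[label_ps(cell)].append(cell)
        _GRID_BY_LABEL = parts
    return _GRID_BY_LABEL


def generate_ratings(label: EmotionLabel, rng: np.random.Generator) -> Ratings:
    """Draw a self-assessment uniformly from the rating-grid cells of the
    requested class; re-labeling the result recovers ``label`` exactly."""
    cells = _grid_by_label()[label]
    return cells[rng.integers(len(cells))]


def _stratified_counts(n: int, mix: tuple[float, ...]) -> list[int]:
    """Largest-remainder allocation of n trials to the mix proportions."""
    raw = [n * p for p in mix]
    counts = [int(np.floor(x)) for x in raw]
    remainder = n - sum(counts)
    order = np.argsort([c - x for c, x in zip(counts, raw)])  # most negative first
    for i in range(remainder):
        counts[order[i]] += 1
    return counts


def generate_cohort(config: GeneratorConfig) -> SyntheticCohort:
    """Generate a full labeled cohort (EEG + ratings), deterministically
    for a given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    n = config.n_trials

    if config.stratified:
        counts = _stratified_counts(n, config.label_mix)
        labels = [lbl for lbl, c in zip(LABEL_ORDER, counts) for _ in range(c)]
        rng.shuffle(labels)
    else:
        idx = rng.choice(3, size=n, p=config.label_mix)
        labels = [LABEL_ORDER[i] for i in idx]

    subject_gains = np.exp(rng.normal(0.0, config.subject_amp_sd, config.n_subjects))

    sessions: list[Session] = []
    k = 0
    for s in range(config.n_subjects):
        subject_id = f"s{s + 1:02d}"
        for t in range(config.n_trials_per_subject):
            label = labels[k]
            ratings = generate_ratings(label, rng)
            recording = generate_trial_eeg(
                label, config, rng, subject_gain=subject_gains[s]
            )
            recording.meta["subject_id"] = subject_id
            recording.meta["trial_index"] = str(t + 1)
            sessions.append(Session(subject_id, t + 1, recording, ratings, label))
            k += 1
    return SyntheticCohort(sessions=sessions, config=config)


def write_cohort(cohort: SyntheticCohort, destination: str | Path) -> dict:
    """Write one OpenBCI-dialect TXT per trial plus one ratings CSV.

    Returns a manifest ``{"txt_files": [...], "ratings_file": path|None}``.
    An empty cohort produces an empty manifest and no files.
    """
    destination = Path(destination)
    if cohort.sessions and not destination.exists():
        destination.mkdir(parents=True)
    txt_files: list[Path] = []
    for session in cohort.sessions:
        name = f"{session.subject_id}_trial{session.trial_index:02d}.txt"
        path = destination / name
        write_openbci_txt(session.recording, path)
        txt_files.append(path)
    ratings_file = None
    if cohort.sessions:
        ratings_file = destination / "ratings.csv"
        write_ratings_csv(cohort.ratings_table(), ratings_file)
    return {"txt_files": txt_files, "ratings_file": ratings_file}
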