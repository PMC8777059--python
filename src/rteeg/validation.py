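"""End-to-end validation harness.

Regenerates the study at desk scale on synthetic data and checks the
pipeline's arithmetic and statistical contracts: cohort cardinality,
trial length through preprocessing, segmentation, fold sizes, I/O
round-trips, the labeling oracle, filter frequency responses, parameter
counts, and classifier recovery of the injected lateralized alpha
effect.

Two profiles are provided.  ``ci`` is the reduced profile meant for a
single CPU: 60 trials (30 positive / 30 negative), segments decimated
750 -> 94 timesteps, a two-layer Bi-LSTM with (16, 8) units, batch 10,
Adam 1e-3, at most 10 epochs.  ``full`` runs the study-scale protocol
(396-trial cohort, 750 timesteps, (64, 32, 16) units) and is orders of
magnitude slower; it exists for completeness, not routine use.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from .dataset import SegmentedDataset, assemble_dataset, segment_trial
from .experiment import (
    CVResult,
    TrainConfig,
    decimate_dataset,
    make_folds,
    run_cv,
)
from .io import read_openbci_txt, read_csv, write_csv, write_openbci_txt
from .labeling import EmotionLabel, label_ps, rating_grid
from .models import ModelSpec, build_model, count_parameters
from .preprocessing import (
    default_bandpass,
    frequency_response_db,
    preprocess_trial,
)
from .synthetic import GeneratorConfig, SyntheticCohort, generate_cohort

__all__ = [
    "AcceptanceCheck",
    "AcceptanceReport",
    "ReducedProfile",
    "process_cohort",
    "make_recovery_dataset",
    "run_acceptance",
]


@dataclass
class AcceptanceCheck:
    name: str
    expected: object
    observed: object
    passed: bool
    provenance: str

    def as_dict(self) -> dict:
        return {
            "name": self.name,
            "expected": self.expected,
            "observed": self.observed,
            "passed": self.passed,
            "provenance": self.provenance,
        }


@dataclass
class AcceptanceReport:
    profile: str
    seed: int
    checks: list[AcceptanceCheck] = field(default_factory=list)
    started: float = field(default_factory=time.time)

    def add(self, name, expected, observed, passed, provenance) -> None:
        self.checks.append(AcceptanceCheck(name, expected, observed, passed, provenance))

    def record(self, name: str, provenance: str, fn) -> None:
        """Run one check; a raising check becomes a failed entry, not a crash."""
        try:
            expected, observed, passed = fn()
        except Exception as exc:  # noqa: BLE001 - report, don't crash
            self.add(name, None, f"error: {exc}", False, provenance)
        else:
            self.add(name, expected, observed, passed, provenance)

    @property
    def all_passed(self) -> bool:
        return all(c.passed for c in self.checks)

    def as_dict(self) -> dict:
        return {
            "profile": self.profile,
            "seed": self.seed,
            "elapsed_s": round(time.time() - self.started, 2),
            "all_passed": self.all_passed,
            "checks": [c.as_dict() for c in self.checks],
        }


@dataclass(frozen=True)
class ReducedProfile:
    """Desk-scale training profile for the recovery checks."""

    n_subjects: int = 6
    n_trials_per_subject: int = 10
    effect_size: float = 1.5
    decimate: int = 8
    layer_units: tuple[int, ...] = (16, 8)
    batch_size: int = 10
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    max_epochs: int = 10
    k_folds: int = 4


def process_cohort(cohort: SyntheticCohort, subset: str = "full") -> SegmentedDataset:
    """Run the standard pipeline on a cohort: label each trial from its
    self-assessment (PS rule), drop excluded trials, preprocess
    (band-pass then detrend), and assemble the segmented dataset."""
    labeled = []
    for s in cohort.sessions:
        label = label_ps(s.ratings)
        if label is EmotionLabel.EXCLUDED:
            continue
        rec = preprocess_trial(s.recording)
        labeled.append((f"{s.subject_id}/{s.trial_index}", rec, label))
    return assemble_dataset(labeled, subset)


def make_recovery_dataset(
    effect_size: float,
    seed: int,
    profile: ReducedProfile = ReducedProfile(),
    subset: str = "full",
) -> SegmentedDataset:
    """Balanced positive/negative synthetic dataset for parameter-recovery
    runs, pushed through the full pipeline and decimated per the profile."""
    config = GeneratorConfig(
        n_subjects=profile.n_subjects,
        n_trials_per_subject=profile.n_trials_per_subject,
        effect_size=effect_size,
        label_mix=(0.5, 0.5, 0.0),
        stratified=True,
        seed=seed,
    )
    ds = process_cohort(generate_cohort(config), subset=subset)
    return decimate_dataset(ds, profile.decimate)


def recovery_cv(
    effect_size: float,
    seed: int,
    profile: ReducedProfile = ReducedProfile(),
    architecture: str = "bilstm",
) -> CVResult:
    """Cross-validated recovery run at the given effect size."""
    ds = make_recovery_dataset(effect_size, seed, profile)
    spec = ModelSpec(
        architecture=architecture,
        layer_units=profile.layer_units,
        input_timesteps=ds.data.shape[2],
        input_channels=ds.data.shape[3],
    )
    cfg = TrainConfig(
        optimizer=profile.optimizer,
        learning_rate=profile.learning_rate,
        batch_size=profile.batch_size,
        max_epochs=profile.max_epochs,
        k_folds=profile.k_folds,
        seed=seed,
    )
    return run_cv(ds, spec, cfg)


def run_acceptance(
    seed: int = 0, profile: str = "ci", tmpdir=None
) -> AcceptanceReport:
    """Execute the whole pipeline at desk scale and report every check.

    ``tmpdir`` (a pathlib.Path) is where I/O round-trip files are
    written; defaults to a fresh temporary directory.
    """
    import tempfile
    from pathlib import Path

    report = AcceptanceReport(profile=profile, seed=seed)
    if tmpdir is None:
        tmpdir = Path(tempfile.mkdtemp(prefix="rteeg-accept-"))

    if profile == "ci":
        prof = ReducedProfile()
        cardinality_cfg = GeneratorConfig(seed=seed)
    elif profile == "full":
        prof = ReducedProfile(
            n_subjects=11, n_trials_per_subject=36, decimate=1,
            layer_units=(64, 32, 16), batch_size=10, max_epochs=50,
        )
        cardinality_cfg = GeneratorConfig(seed=seed)
    else:
        raise ValueError(f"unknown profile {profile!r}")

    # --- cohort cardinality (11 x 36 = 396 at defaults) ------------------
    state: dict = {}

    def check_cardinality():
        cohort = generate_cohort(cardinality_cfg)
        state["cohort"] = cohort
        return 396, len(cohort), len(cohort) == 396

    report.record("cohort_cardinality", "11 subjects x 36 conversations", check_cardinality)

    # --- trial length through preprocessing ------------------------------
    def check_trial_length():
        session = state["cohort"].sessions[0]
        cleaned = preprocess_trial(session.recording)
        state["cleaned"] = cleaned
        ok = session.recording.n_samples == 15000 and cleaned.n_samples == 15000
        return 15000, cleaned.n_samples, ok

    report.record("trial_samples", "60 s x 250 Hz preserved by filtering", check_trial_length)

    # --- segmentation -----------------------------------------------------
    def check_segmentation():
        cleaned = state["cleaned"]
        segs = segment_trial(cleaned.samples, cleaned.fs)
        recon = segs.transpose(2, 0, 1).reshape(cleaned.samples.shape)
        ok = segs.shape == (20, 750, 8) and np.array_equal(recon, cleaned.samples)
        return (20, 750, 8), segs.shape, ok

    report.record("segmentation", "20 contiguous 3-s segments, lossless", check_segmentation)

    # --- fold sizes -------------------------------------------------------
    def check_folds():
        folds = make_folds(195, 4, seed=seed)
        sizes = sorted(folds.sizes(), reverse=True)
        train_sizes = sorted(
            (len(folds.fold_indices(f)[0]) for f in range(4)), reverse=False
        )
        ok = sizes == [49, 49, 49, 48] and train_sizes == [146, 146, 146, 147]
        return [49, 49, 49, 48], sizes, ok

    report.record("cv_fold_sizes", "195 trials into 4 near-equal folds", check_folds)

    # --- I/O round-trip ---------------------------------------------------
    def check_io():
        rec = state["cohort"].sessions[0].recording
        txt = tmpdir / "trial.txt"
        csv = tmpdir / "trial.csv"
        write_openbci_txt(rec, txt)
        back = read_openbci_txt(txt)
        write_csv(back, csv)
        back2 = read_csv(csv, fs=back.fs)
        ok = (
            back.n_channels == 8
            and np.array_equal(back.samples, rec.samples)
            and np.array_equal(back2.samples, rec.samples)
        )
        return "lossless", "lossless" if ok else "mismatch", ok

    report.record("io_roundtrip", "TXT -> memory -> CSV -> memory", check_io)

    # --- labeling oracle --------------------------------------------------
    def check_labeling():
        counts = {label: 0 for label in EmotionLabel}
        for cell in rating_grid():
            counts[label_ps(cell)] += 1
        observed = (
            counts[EmotionLabel.POSITIVE],
            counts[EmotionLabel.NEGATIVE],
            counts[EmotionLabel.EXCLUDED],
        )
        return (36, 477, 54), observed, observed == (36, 477, 54)

    report.record("labeling_cell_counts", "exhaustive 567-cell enumeration", check_labeling)

    # --- filter responses -------------------------------------------------
    def check_filters():
        bp = default_bandpass()
        att60 = -frequency_response_db(bp, 250.0, np.array([60.0]))[0]
        gain10 = frequency_response_db(bp, 250.0, np.array([10.0]))[0]
        ok = att60 >= 40.0 and abs(gain10) <= 1.0
        return ">=40 dB @60Hz, |gain@10Hz|<=1 dB", (round(float(att60), 1), round(float(gain10), 3)), ok

    report.record("bandpass_response", "analytic frequency-response oracle", check_filters)

    def check_detrend():
        fs, dur = 250.0, 60.0
        n = int(fs * dur)
        t = np.arange(n) / fs
        ramp = 50.0 * t / dur
        from .io import RawRecording

        rec = RawRecording(samples=ramp[None, :], fs=fs, montage=("F3",))
        out = preprocess_trial(rec)
        sl = slice(int(fs), n - int(fs))  # exclude 1-s edge transients
        slope_in = np.polyfit(t[sl], ramp[sl], 1)[0]
        slope_out = np.polyfit(t[sl], out.samples[0, sl], 1)[0]
        ratio = abs(slope_out / slope_in)
        return "<1% residual slope", round(float(100 * ratio), 4), ratio < 0.01

    report.record("detrend_ramp", "least-squares slope oracle", check_detrend)

    # --- parameter counts -------------------------------------------------
    def check_params():
        observed = []
        ok = True
        for arch in ("lstm", "bilstm"):
            for units in ((1,), (2, 1), (4, 2)):
                for ch in (1, 2):
                    spec = ModelSpec(
                        architecture=arch, layer_units=units,
                        input_timesteps=8, input_channels=ch,
                    )
                    built = build_model(spec, rng=seed).n_parameters
                    closed = count_parameters(spec)
                    ok &= built == closed
        first_layer = 4 * ((8 + 64 + 1) * 64)
        observed.append(first_layer)
        ok &= first_layer == 18688
        return 18688, first_layer, ok

    report.record("parameter_counts", "closed-form vs constructed models", check_params)

    # --- classifier recovery ---------------------------------------------
    def check_recovery_strong():
        result = recovery_cv(1.5, seed, prof, architecture="bilstm")
        state["strong"] = result
        return ">=0.85", round(result.mean_accuracy, 4), result.mean_accuracy >= 0.85

    report.record(
        "cv_recovery_strong_effect",
        "Bi-LSTM fourfold CV on injected alpha asymmetry (delta=1.5)",
        check_recovery_strong,
    )

    def check_recovery_null():
        result = recovery_cv(0.0, seed, prof, architecture="bilstm")
        state["null"] = result
        ds = make_recovery_dataset(0.0, seed, prof)
        # segments within a trial are correlated; the trial count is the
        # effective sample size for the interval
        p0 = max(ds.class_counts()) / ds.n_trials
        half = 1.96 * np.sqrt(p0 * (1 - p0) / ds.n_trials)
        acc = result.mean_accuracy
        ok = (p0 - half) <= acc <= (p0 + half)
        return f"{p0:.3f} +/- {half:.3f}", round(acc, 4), ok

    report.record(
        "cv_null_effect",
        "delta=0 accuracy within 95% binomial interval of majority baseline",
        check_recovery_null,
    )

    # --- determinism ------------------------------------------------------
    def check_determinism():
        micro = ReducedProfile(
            n_subjects=2, n_trials_per_subject=6, decimate=9,
            layer_units=(8, 4), batch_size=20, max_epochs=3, k_folds=4,
        )
        a = recovery_cv(1.0, seed, micro, architecture="lstm")
        b = recovery_cv(1.0, seed, micro, architecture="lstm")
        same = (
            a.fold_accuracies == b.fold_accuracies
            and a.early_stop_epochs == b.early_stop_epochs
            and a.selected_epoch == b.selected_epoch
            and a.mean_accuracy == b.mean_accuracy
        )
        return "identical CVResult", "identical" if same else "diverged", same

    report.record("determinism", "same master seed reproduces CVResult", check_determinism)

    state.pop("cohort", None)
    return report
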