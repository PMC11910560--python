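"""Synthetic multi-channel EEG cohort generator.

Emulates a four-task motor-imagery recording session: three scalp channels
(T3, T4, FP1), 5-second trials at a fixed sampling rate, four imagery tasks
(forward / left / right / stop), a configurable number of subjects and trials
per task, 50 Hz mains contamination and additive Gaussian noise.  Each task
leaves a distinct spectral fingerprint — a gain applied to one
(channel, frequency-band) pair — so that band-power features carry class
information without making the problem trivially separable.

Every trial is generated from its own random substream keyed by
(root seed, subject, label, trial index), so a cohort is bit-reproducible
regardless of the order in which trials are materialised.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

TASKS: tuple[str, ...] = ("forward", "left", "right", "stop")
CHANNELS: tuple[str, ...] = ("T3", "T4", "FP1")

#: canonical EEG rhythm bands (Hz) used to synthesise the oscillatory content
RHYTHM_BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
}

#: default task signatures: each task boosts one distinct (channel, band) pair
DEFAULT_SIGNATURE_PAIRS: dict[str, tuple[str, str]] = {
    "forward": ("T3", "alpha"),
    "left": ("T4", "alpha"),
    "right": ("T3", "beta"),
    "stop": ("T4", "beta"),
}

TRIAL_SECONDS = 5.0
_OSC_PER_BAND = 3  # sinusoids drawn per rhythm band


@dataclass(frozen=True)
class Trial:
    """One labelled EEG epoch: the unit of classification.

    ``samples`` is a (channels x time) float array in microvolt-like units,
    rows ordered as :data:`CHANNELS`.
    """

    samples: np.ndarray
    fs: float
    label: str
    subject_id: str
    trial_index: int
    mode: str = "offline"

    def __post_init__(self) -> None:
        if self.label not in TASKS:
            raise ValueError(f"unknown task label {self.label!r}; expected one of {TASKS}")
        if self.mode not in ("offline", "online"):
            raise ValueError(f"mode must be 'offline' or 'online', got {self.mode!r}")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.samples.ndim != 2 or self.samples.shape[0] != len(CHANNELS):
            raise ValueError(
                f"samples must be ({len(CHANNELS)} x n_times), got {self.samples.shape}"
            )
        expected = int(round(TRIAL_SECONDS * self.fs))
        if self.samples.shape[1] != expected:
            raise ValueError(
                f"trial must hold exactly {TRIAL_SECONDS:g} s of data "
                f"({expected} samples at fs={self.fs:g}), got {self.samples.shape[1]}"
            )

    @property
    def n_times(self) -> int:
        return self.samples.shape[1]

    def with_samples(self, samples: np.ndarray) -> "Trial":
        return dataclasses.replace(self, samples=samples)


def default_class_signatures(gain: float = 2.0) -> dict[str, dict[tuple[str, str], float]]:
    """Per-task map of (channel, band) -> excess relative power gain.

    Each of the four tasks boosts one distinct (channel, band) pair: the
    pair's oscillatory power is multiplied by ``1 + gain`` (amplitude by
    ``sqrt(1 + gain)``).  ``gain = 0`` therefore means no class-dependent
    structure at all — every task produces statistically identical signals —
    and increasing ``gain`` monotonically increases class separability.
    """
    return {task: {pair: gain} for task, pair in DEFAULT_SIGNATURE_PAIRS.items()}


def null_class_signatures() -> dict[str, dict[tuple[str, str], float]]:
    """Signatures with no class-dependent structure (all excess gains 0)."""
    return default_class_signatures(gain=0.0)


@dataclass
class CohortSpec:
    """Study-design parameters of a synthetic recording session."""

    n_subjects: int = 18
    trials_per_task: int = 10
    tasks: tuple[str, ...] = TASKS
    fs: float = 256.0
    seed: int = 0
    class_signatures: dict[str, dict[tuple[str, str], float]] = field(
        default_factory=default_class_signatures
    )
    line_noise_amplitude: float = 20.0
    noise_sd: float = 4.0
    base_amplitude: float = 10.0
    #: multiplier on noise_sd for online-mode trials (live sessions are noisier)
    online_noise_factor: float = 1.25
    #: sd of the per-subject multiplicative amplitude jitter
    subject_jitter_sd: float = 0.05
    #: rhythm bands actually synthesised (subset of RHYTHM_BANDS keys)
    active_bands: tuple[str, ...] = ("delta", "theta", "alpha", "beta")

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.trials_per_task < 1:
            raise ValueError("n_subjects and trials_per_task must be >= 1")
        if len(self.tasks) != 4:
            raise ValueError("exactly four tasks are required")
        if self.fs <= 100.0:
            raise ValueError("fs must exceed 100 Hz so the 50 Hz mains line is representable")
        # non-null signatures must be pairwise distinct; tasks with no excess
        # gain anywhere (the null signature) may coincide
        sigs = [
            tuple(sorted((k, v) for k, v in self.class_signatures.get(t, {}).items() if v != 0.0))
            for t in self.tasks
        ]
        non_null = [s for s in sigs if s]
        if len(set(non_null)) < len(non_null):
            raise ValueError("class signatures must differ between tasks")

    @property
    def n_trials(self) -> int:
        return self.n_subjects * len(self.tasks) * self.trials_per_task

    def subject_ids(self) -> list[str]:
        return [f"S{i + 1:02d}" for i in range(self.n_subjects)]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["tasks"] = list(self.tasks)
        d["class_signatures"] = {
            task: {f"{ch}:{band}": g for (ch, band), g in pairs.items()}
            for task, pairs in self.class_signatures.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        d = dict(d)
        d["tasks"] = tuple(d.get("tasks", TASKS))
        if "active_bands" in d:
            d["active_bands"] = tuple(d["active_bands"])
        sigs = d.get("class_signatures")
        if sigs is not None:
            d["class_signatures"] = {
                task: {tuple(key.split(":")): g for key, g in pairs.items()}
                for task, pairs in sigs.items()
            }
        return cls(**d)


def _trial_rng(spec: CohortSpec, subject_id: str, label: str, trial_index: int) -> np.random.Generator:
    sub = int(subject_id.lstrip("S")) if subject_id.startswith("S") else abs(hash(subject_id)) % 2**16
    key = (spec.seed, sub, spec.tasks.index(label), trial_index)
    return np.random.default_rng(np.random.SeedSequence(key))


def _subject_gain(spec: CohortSpec, subject_id: str) -> float:
    sub = int(subject_id.lstrip("S")) if subject_id.startswith("S") else abs(hash(subject_id)) % 2**16
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 10_007, sub)))
    return float(max(0.5, 1.0 + spec.subject_jitter_sd * rng.standard_normal()))


def generate_trial(
    spec: CohortSpec,
    subject_id: str,
    label: str,
    trial_index: int,
    mode: str = "offline",
) -> Trial:
    """Synthesise one labelled trial.

    The per-channel signal is a sum of band-limited oscillations (three
    random-frequency sinusoids per rhythm band, task-specific amplitude gain
    on the signature pair), plus white Gaussian noise and a 50 Hz mains
    sinusoid.  Fully determined by (spec.seed, subject_id, label,
    trial_index, mode).
    """
    if label not in spec.tasks:
        raise ValueError(f"unknown label {label!r}; tasks are {spec.tasks}")
    rng = _trial_rng(spec, subject_id, label, trial_index)
    n = int(round(TRIAL_SECONDS * spec.fs))
    t = np.arange(n) / spec.fs
    gains = spec.class_signatures.get(label, {})
    subj_gain = _subject_gain(spec, subject_id)

    samples = np.zeros((len(CHANNELS), n))
    for ci, ch in enumerate(CHANNELS):
        x = np.zeros(n)
        for band in spec.active_bands:
            lo, hi = RHYTHM_BANDS[band]
            excess = gains.get((ch, band), 0.0)
            amp = spec.base_amplitude * np.sqrt(1.0 + excess) * subj_gain / _OSC_PER_BAND
            freqs = rng.uniform(lo, hi, size=_OSC_PER_BAND)
            phases = rng.uniform(0.0, 2.0 * np.pi, size=_OSC_PER_BAND)
            x += (amp * np.sin(2.0 * np.pi * freqs[:, None] * t[None, :] + phases[:, None])).sum(axis=0)
        noise_sd = spec.noise_sd * (spec.online_noise_factor if mode == "online" else 1.0)
        if noise_sd > 0:
            x += noise_sd * rng.standard_normal(n)
        else:
            rng.standard_normal(n)  # keep the stream aligned across noise settings
        if spec.line_noise_amplitude > 0:
            x += spec.line_noise_amplitude * np.sin(2.0 * np.pi * 50.0 * t + rng.uniform(0, 2 * np.pi))
        else:
            rng.uniform(0, 2 * np.pi)
        samples[ci] = x

    return Trial(
        samples=samples,
        fs=spec.fs,
        label=label,
        subject_id=subject_id,
        trial_index=trial_index,
        mode=mode,
    )


def _trial_order(spec: CohortSpec, subject_id: str, mode: str) -> list[tuple[str, int]]:
    """(label, trial_index) sequence for one subject's session.

    Offline sessions cue tasks in fixed contiguous blocks; online sessions cue
    them in a seeded-random order.
    """
    blocks = [(task, k) for task in spec.tasks for k in range(1, spec.trials_per_task + 1)]
    if mode == "offline":
        return blocks
    sub = int(subject_id.lstrip("S")) if subject_id.startswith("S") else abs(hash(subject_id)) % 2**16
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 20_011, sub)))
    perm = rng.permutation(len(blocks))
    return [blocks[i] for i in perm]


def generate_cohort(spec: CohortSpec, mode: str = "offline") -> tuple[list[Trial], pd.DataFrame]:
    """Generate the full cohort and its manifest.

    Returns the trials (in session order) and a manifest DataFrame with
    columns subject_id, label, trial_index, order, mode.
    """
    if mode not in ("offline", "online"):
        raise ValueError("mode must be 'offline' or 'online'")
    trials: list[Trial] = []
    rows = []
    for subject_id in spec.subject_ids():
        for order, (label, k) in enumerate(_trial_order(spec, subject_id, mode)):
            trials.append(generate_trial(spec, subject_id, label, k, mode))
            rows.append(
                {"subject_id": subject_id, "label": label, "trial_index": k, "order": order, "mode": mode}
            )
    return trials, pd.DataFrame(rows)


def iter_cohort(spec: CohortSpec, mode: str = "offline") -> Iterator[Trial]:
    for subject_id in spec.subject_ids():
        for label, k in _trial_order(spec, subject_id, mode):
            yield generate_trial(spec, subject_id, label, k, mode)


# ---------------------------------------------------------------------------
# on-disk cohort format: one TSV per trial + manifest.tsv + cohort.json
# ---------------------------------------------------------------------------

def write_cohort(spec: CohortSpec, out_dir: str | Path, mode: str = "offline") -> pd.DataFrame:
    """Write a cohort directory: per-trial TSV files, a manifest and the spec."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    trials, manifest = generate_cohort(spec, mode)
    paths = []
    for trial in trials:
        name = f"{trial.subject_id}_{trial.label}_{trial.trial_index:02d}_{trial.mode}.tsv"
        df = pd.DataFrame(trial.samples.T, columns=list(CHANNELS))
        df.to_csv(out / name, sep="\t", index=False, float_format="%.6f")
        paths.append(name)
    manifest = manifest.assign(path=paths, fs=spec.fs)
    manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
    (out / "cohort.json").write_text(json.dumps(spec.to_dict(), indent=2))
    return manifest


def read_cohort(cohort_dir: str | Path) -> tuple[list[Trial], pd.DataFrame, CohortSpec]:
    """Load a cohort directory written by :func:`write_cohort`."""
    root = Path(cohort_dir)
    spec = CohortSpec.from_dict(json.loads((root / "cohort.json").read_text()))
    manifest = pd.read_csv(root / "manifest.tsv", sep="\t")
    trials = []
    for row in manifest.itertuples():
        df = pd.read_csv(root / row.path, sep="\t")
        trials.append(
            Trial(
                samples=df[list(CHANNELS)].to_numpy().T,
                fs=float(row.fs),
                label=row.label,
                subject_id=row.subject_id,
                trial_index=int(row.trial_index),
                mode=row.mode,
            )
        )
    return trials, manifest, spec
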