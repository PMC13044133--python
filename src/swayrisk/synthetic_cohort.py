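"""Synthetic posturography cohorts with the study's structure.

The generator emulates a 32-patient Parkinson's-disease balance study:
8 fall-risk and 24 no-fall-risk subjects (Mini-BESTest <= 21 defines risk),
four standing conditions (rigid/unstable surface x eyes open/closed), three
30-s trials per condition sampled at 100 Hz, with AP and ML COP channels.

Each COP axis is synthesised as a sum of three independent band-limited
filtered-noise processes — slow drift (~0.01-0.3 Hz), a mid band
(~0.3-1.5 Hz) and a high band (~1.5-8 Hz) — so the signal populates several
distinct oscillatory scales and empirical mode decomposition reliably yields
five stable modes.  All energy sits below 10 Hz, making the low-pass
preprocessing near-transparent.

Group differences are injected only in the high band, mirroring the observed
effect directions: at-risk subjects have a *smaller* high-band amplitude
(more constrained fine-scale sway, hence lower IMF1 dispersion) and a
*heavy-tailed* high band (blockwise Gaussian scale-mixture modulation, hence
positive excess IMF1 kurtosis).  Magnitudes are not calibrated to any real
cohort; only the signs of the effects are contractual.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from .signal_prep import CopTrial

__all__ = [
    "EffectSpec",
    "CohortSpec",
    "SubjectProfile",
    "CohortDataset",
    "CohortFormatError",
    "generate_trial",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
]

CONDITIONS = ("rs_eo", "rs_ec", "us_eo", "us_ec")

#: Frequency bands (Hz) of the three stochastic components.
BANDS = {"drift": (0.01, 0.3), "mid": (0.3, 1.5), "high": (1.5, 8.0)}

#: Baseline per-band COP standard deviations (cm) for a no-risk subject in
#: the reference condition.  AP sway exceeds ML sway by roughly 3x, as is
#: typical of quiet standing; the high band dominates so that IMF1 carries a
#: visible share of the signal.
BASE_AMPLITUDE = {
    "ap": {"drift": 0.35, "mid": 0.20, "high": 0.60},
    "ml": {"drift": 0.12, "mid": 0.07, "high": 0.20},
}

#: Between-subject lognormal sd of band amplitudes.
SUBJECT_SD = 0.25

#: Scale-mixture parameters for the at-risk heavy-tailed high band: a block
#: has probability ``_MIX_P`` of amplitude inflation by ``_MIX_C``; blocks
#: are 0.25 s long.  Gives excess kurtosis ~ +5 before normalisation.
_MIX_P = 0.10
_MIX_C = 3.0
_BLOCK_SECONDS = 0.25

MINI_BEST_CUTOFF = 21


class CohortFormatError(ValueError):
    """Raised when a stored cohort violates the dataset contract."""


@dataclass
class EffectSpec:
    """Injected group-difference parameters (all multiplicative scales > 0)."""

    hf_amp_ratio: float = 0.45
    kurtosis_boost: bool = True
    drift_scale: float = 1.0
    trial_jitter: float = 0.15
    condition_gain: dict[str, float] = field(
        default_factory=lambda: {"rs_eo": 1.0, "rs_ec": 1.3, "us_eo": 1.8, "us_ec": 2.2}
    )

    def __post_init__(self) -> None:
        if self.hf_amp_ratio <= 0 or self.drift_scale <= 0 or self.trial_jitter < 0:
            raise ValueError("effect scales must be positive")
        if any(g <= 0 for g in self.condition_gain.values()):
            raise ValueError("condition gains must be positive")

    @classmethod
    def null(cls) -> "EffectSpec":
        """No injected group difference (for calibration studies)."""
        return cls(hf_amp_ratio=1.0, kurtosis_boost=False)


@dataclass
class CohortSpec:
    """Study-design parameters of a synthetic cohort."""

    n_fall_risk: int = 8
    n_no_risk: int = 24
    conditions: tuple[str, ...] = CONDITIONS
    trials_per_condition: int = 3
    duration: float = 30.0
    fs: float = 100.0
    effect: EffectSpec = field(default_factory=EffectSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fall_risk < 1 or self.n_no_risk < 1:
            raise ValueError("need at least one subject per group")
        if self.trials_per_condition < 1:
            raise ValueError("trials_per_condition must be >= 1")
        n = self.duration * self.fs
        if abs(n - round(n)) > 1e-9 or n < 256:
            raise ValueError("duration*fs must be an integer >= 256")
        unknown = set(self.conditions) - set(CONDITIONS)
        if unknown:
            raise ValueError(f"unknown condition codes: {sorted(unknown)}")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.fs))

    @property
    def n_subjects(self) -> int:
        return self.n_fall_risk + self.n_no_risk


@dataclass
class SubjectProfile:
    """Per-subject draw of band amplitudes, label and balance score."""

    subject_id: str
    at_risk: bool
    mini_best_score: int
    band_amplitude: dict[str, dict[str, float]]  # axis -> band -> cm


@dataclass
class CohortDataset:
    """Trials plus subject metadata and generation provenance."""

    trials: list[CopTrial]
    subjects: dict[str, tuple[int, str]]  # subject_id -> (mini_best, label)
    spec: CohortSpec | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        for sid, (score, label) in self.subjects.items():
            want = "fall_risk" if score <= MINI_BEST_CUTOFF else "no_fall_risk"
            if label != want:
                raise CohortFormatError(
                    f"subject {sid}: score {score} inconsistent with label {label}"
                )
        ids = [t.trial_id for t in self.trials]
        if len(ids) != len(set(ids)):
            raise CohortFormatError("duplicate trial IDs")

    def label(self, subject_id: str) -> str:
        return self.subjects[subject_id][1]

    @property
    def conditions(self) -> list[str]:
        seen = dict.fromkeys(t.condition for t in self.trials)
        return list(seen)

    def trials_for(self, condition: str | None = None) -> list[CopTrial]:
        if condition is None:
            return list(self.trials)
        return [t for t in self.trials if t.condition == condition]

    def validate_structure(self, trials_per_condition: int) -> None:
        """Check every (subject, condition) cell holds the full trial count."""
        counts: dict[tuple[str, str], int] = {}
        for t in self.trials:
            counts[(t.subject_id, t.condition)] = counts.get((t.subject_id, t.condition), 0) + 1
        for (sid, cond), c in counts.items():
            if c != trials_per_condition:
                raise CohortFormatError(
                    f"subject {sid}, condition {cond}: {c} trials, "
                    f"expected {trials_per_condition}"
                )


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _band_noise(n: int, fs: float, band: tuple[float, float], rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited to ``band`` (Hz)."""
    lo, hi = band
    sos = butter(2, [lo, hi], btype="band", fs=fs, output="sos")
    # Pad generously so the narrow drift band settles.
    pad = min(4 * n, int(20 * fs / lo))
    w = rng.standard_normal(n + 2 * pad)
    y = sosfiltfilt(sos, w)[pad:pad + n]
    sd = np.std(y)
    return y / sd if sd > 0 else y


def _heavy_tail_modulation(n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Blockwise scale-mixture envelope giving positive excess kurtosis.

    Each 0.25-s block is amplified by ``_MIX_C`` with probability ``_MIX_P``;
    the envelope is normalised to unit mean-square so it changes the shape of
    the amplitude distribution without changing the band's variance.
    """
    block = max(1, int(round(_BLOCK_SECONDS * fs)))
    n_blocks = -(-n // block)
    scales = np.where(rng.random(n_blocks) < _MIX_P, _MIX_C, 1.0)
    env = np.repeat(scales, block)[:n]
    return env / np.sqrt(np.mean(env**2))


def generate_trial(
    profile: SubjectProfile,
    condition: str,
    rng: np.random.Generator,
    spec: CohortSpec,
    trial_index: int = 1,
) -> CopTrial:
    """One trial: three band-limited components per axis, summed.

    The subject's per-band amplitudes (drawn once per subject) are scaled by
    the condition gain and a per-trial lognormal jitter; the at-risk high
    band additionally receives the heavy-tailed envelope when
    ``kurtosis_boost`` is on.
    """
    eff = spec.effect
    n, fs = spec.n_samples, spec.fs
    gain = eff.condition_gain.get(condition, 1.0)
    axes: dict[str, np.ndarray] = {}
    for axis in ("ap", "ml"):
        total = np.zeros(n)
        for band_name, band in BANDS.items():
            amp = profile.band_amplitude[axis][band_name] * gain
            if band_name == "drift":
                amp *= eff.drift_scale
            if eff.trial_jitter > 0:
                amp *= rng.lognormal(mean=0.0, sigma=eff.trial_jitter)
            comp = _band_noise(n, fs, band, rng)
            if band_name == "high" and profile.at_risk and eff.kurtosis_boost:
                comp = comp * _heavy_tail_modulation(n, fs, rng)
            total = total + amp * comp
        axes[axis] = total
    return CopTrial(
        subject_id=profile.subject_id,
        condition=condition,
        trial_index=trial_index,
        fs=fs,
        cop_ap=axes["ap"],
        cop_ml=axes["ml"],
    )


def _draw_profile(sid: str, at_risk: bool, spec: CohortSpec, rng: np.random.Generator) -> SubjectProfile:
    amps: dict[str, dict[str, float]] = {}
    for axis, bands in BASE_AMPLITUDE.items():
        amps[axis] = {}
        for band_name, base in bands.items():
            amp = base * rng.lognormal(mean=0.0, sigma=SUBJECT_SD)
            if band_name == "high" and at_risk:
                amp *= spec.effect.hf_amp_ratio
            amps[axis][band_name] = amp
    lo, hi = (10, MINI_BEST_CUTOFF) if at_risk else (MINI_BEST_CUTOFF + 1, 28)
    score = int(rng.integers(lo, hi + 1))
    return SubjectProfile(
        subject_id=sid,
        at_risk=at_risk,
        mini_best_score=score,
        band_amplitude=amps,
    )


def generate_cohort(spec: CohortSpec | None = None) -> CohortDataset:
    """Full cohort: every subject x condition x repeat, labels by the <=21 rule."""
    spec = spec or CohortSpec()
    rng = np.random.default_rng(spec.seed)
    risk_flags = [True] * spec.n_fall_risk + [False] * spec.n_no_risk
    trials: list[CopTrial] = []
    subjects: dict[str, tuple[int, str]] = {}
    for i, at_risk in enumerate(risk_flags, start=1):
        sid = f"S{i:02d}"
        profile = _draw_profile(sid, at_risk, spec, rng)
        subjects[sid] = (
            profile.mini_best_score,
            "fall_risk" if at_risk else "no_fall_risk",
        )
        for cond in spec.conditions:
            for rep in range(1, spec.trials_per_condition + 1):
                trials.append(generate_trial(profile, cond, rng, spec, trial_index=rep))
    ds = CohortDataset(trials=trials, subjects=subjects, spec=spec, seed=spec.seed)
    ds.validate_structure(spec.trials_per_condition)
    return ds


# ---------------------------------------------------------------------------
# on-disk format: two CSVs (samples long-format + subjects)
# ---------------------------------------------------------------------------

def write_cohort(dataset: CohortDataset, path: str | Path) -> None:
    """Write ``samples.csv`` (long format) and ``subjects.csv`` under ``path``.

    COP in cm, time in seconds, UTF-8, '.' decimal, no index column.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    frames = []
    for t in dataset.trials:
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": t.subject_id,
                    "condition": t.condition,
                    "trial": t.trial_index,
                    "t": np.arange(t.n_samples) / t.fs,
                    "cop_ap": t.cop_ap,
                    "cop_ml": t.cop_ml,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path / "samples.csv", index=False)
    subj = pd.DataFrame(
        [
            {"subject_id": sid, "mini_best": score, "label": label}
            for sid, (score, label) in dataset.subjects.items()
        ]
    )
    subj.to_csv(path / "subjects.csv", index=False)


def read_cohort(path: str | Path, trials_per_condition: int | None = None) -> CohortDataset:
    """Read a cohort written by :func:`write_cohort`, revalidating invariants."""
    path = Path(path)
    samples_file = path / "samples.csv"
    subjects_file = path / "subjects.csv"
    try:
        samples = pd.read_csv(samples_file)
        subj = pd.read_csv(subjects_file)
    except (pd.errors.ParserError, FileNotFoundError) as exc:
        raise CohortFormatError(f"cannot read cohort at {path}: {exc}") from exc

    need = {"subject_id", "condition", "trial", "t", "cop_ap", "cop_ml"}
    if not need.issubset(samples.columns):
        raise CohortFormatError(
            f"{samples_file}: missing columns {sorted(need - set(samples.columns))}"
        )
    subjects: dict[str, tuple[int, str]] = {}
    for row in subj.itertuples(index=False):
        score = int(row.mini_best)
        label = "fall_risk" if score <= MINI_BEST_CUTOFF else "no_fall_risk"
        if str(row.label) != label:
            raise CohortFormatError(
                f"{subjects_file}: subject {row.subject_id} label {row.label!r} "
                f"inconsistent with score {score}"
            )
        subjects[str(row.subject_id)] = (score, label)

    trials: list[CopTrial] = []
    for (sid, cond, rep), g in samples.groupby(
        ["subject_id", "condition", "trial"], sort=True
    ):
        g = g.sort_values("t")
        dt = np.diff(g["t"].to_numpy())
        fs = 1.0 / np.median(dt) if len(dt) else 100.0
        trials.append(
            CopTrial(
                subject_id=str(sid),
                condition=str(cond),
                trial_index=int(rep),
                fs=float(round(fs, 6)),
                cop_ap=g["cop_ap"].to_numpy(),
                cop_ml=g["cop_ml"].to_numpy(),
            )
        )
    ds = CohortDataset(trials=trials, subjects=subjects)
    if trials_per_condition is None:
        per_cell = {}
        for t in trials:
            per_cell.setdefault((t.subject_id, t.condition), 0)
            per_cell[(t.subject_id, t.condition)] += 1
        if per_cell:
            counts = set(per_cell.values())
            if len(counts) > 1:
                bad = [k for k, v in per_cell.items() if v != max(counts)]
                raise CohortFormatError(
                    f"uneven trial counts; first offending (subject, condition): {bad[0]}"
                )
    else:
        ds.validate_structure(trials_per_condition)
    return ds
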