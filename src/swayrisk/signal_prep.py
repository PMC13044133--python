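"""Center-of-pressure computation and low-pass preprocessing.

Quiet-standing posturography records ground reaction forces and moments on a
force plate; the center of pressure (COP) is the point of application of the
resultant vertical force.  With the vertical force ``Fz`` (N) and the moments
``Mx``, ``My`` (N·m) about the plate axes, the COP excursions are ``Mx/Fz``
(anterior-posterior, AP) and ``-My/Fz`` (medio-lateral, ML), reported here in
centimetres.  Raw COP series are smoothed with a fourth-order zero-phase
Butterworth low-pass filter (10 Hz cutoff) before any decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt

__all__ = [
    "CopTrial",
    "ForcePlateRecord",
    "DegenerateLoadingError",
    "cop_from_forces",
    "lowpass_zero_phase",
    "preprocess_trial",
]

#: Minimum trial length in samples accepted anywhere downstream.
MIN_TRIAL_SAMPLES = 256

#: Default low-pass cutoff (Hz) and design order for COP smoothing.
DEFAULT_CUTOFF_HZ = 10.0
DEFAULT_FILTER_ORDER = 4


class DegenerateLoadingError(ValueError):
    """Raised when the vertical force is non-positive (plate unloaded)."""

    def __init__(self, bad_indices: np.ndarray):
        self.bad_indices = np.asarray(bad_indices)
        head = ", ".join(map(str, self.bad_indices[:10]))
        more = "…" if self.bad_indices.size > 10 else ""
        super().__init__(
            f"non-positive vertical force at {self.bad_indices.size} "
            f"sample(s): indices [{head}{more}]"
        )


@dataclass
class CopTrial:
    """One trial's AP and ML COP displacement series (cm) with metadata."""

    subject_id: str
    condition: str
    trial_index: int  # 1-based
    fs: float
    cop_ap: np.ndarray
    cop_ml: np.ndarray

    def __post_init__(self) -> None:
        self.cop_ap = np.asarray(self.cop_ap, dtype=float)
        self.cop_ml = np.asarray(self.cop_ml, dtype=float)
        if self.cop_ap.shape != self.cop_ml.shape or self.cop_ap.ndim != 1:
            raise ValueError("cop_ap and cop_ml must be 1-D and equal length")
        if len(self.cop_ap) < MIN_TRIAL_SAMPLES:
            raise ValueError(
                f"trial shorter than {MIN_TRIAL_SAMPLES} samples: {len(self.cop_ap)}"
            )
        if not (np.isfinite(self.cop_ap).all() and np.isfinite(self.cop_ml).all()):
            raise ValueError("COP series contain non-finite samples")

    @property
    def n_samples(self) -> int:
        return len(self.cop_ap)

    @property
    def trial_id(self) -> str:
        return f"{self.subject_id}/{self.condition}/{self.trial_index}"


@dataclass
class ForcePlateRecord:
    """Raw force-plate channels: vertical force and plate-axis moments."""

    fz: np.ndarray  # N
    mx: np.ndarray  # N·m
    my: np.ndarray  # N·m
    fs: float = 100.0

    def __post_init__(self) -> None:
        self.fz = np.asarray(self.fz, dtype=float)
        self.mx = np.asarray(self.mx, dtype=float)
        self.my = np.asarray(self.my, dtype=float)
        if not (self.fz.shape == self.mx.shape == self.my.shape):
            raise ValueError("fz, mx, my must share a shape")


def cop_from_forces(rec: ForcePlateRecord) -> tuple[np.ndarray, np.ndarray]:
    """COP excursions (cm) from force-plate channels.

    AP is positive anterior (``100·Mx/Fz``), ML positive right
    (``100·(-My)/Fz``); the plate-to-body axis mapping is a loader concern.
    All extracted features except skewness are invariant to a global sign
    flip, so the convention matters only for sign-bearing statistics.
    """
    bad = np.flatnonzero(rec.fz <= 0)
    if bad.size:
        raise DegenerateLoadingError(bad)
    cop_ap = 100.0 * rec.mx / rec.fz
    cop_ml = 100.0 * (-rec.my) / rec.fz
    return cop_ap, cop_ml


def lowpass_zero_phase(
    x: np.ndarray,
    fs: float,
    cutoff: float = DEFAULT_CUTOFF_HZ,
    order: int = DEFAULT_FILTER_ORDER,
) -> np.ndarray:
    """Zero-phase Butterworth low-pass filter (forward-backward).

    The filter is designed at the requested order and applied forward and
    backward, so the effective magnitude response is ``|H(f)|^2`` and the
    phase is exactly zero.  Odd-symmetric edge padding (scipy's default, of
    length three times the filter state length) suppresses end transients.
    """
    x = np.asarray(x, dtype=float)
    if cutoff >= fs / 2:
        raise ValueError(f"cutoff {cutoff} Hz must be below Nyquist {fs / 2} Hz")
    if len(x) <= 3 * order:
        raise ValueError(f"series too short to filter: {len(x)} samples")
    b, a = butter(order, cutoff, btype="low", fs=fs)
    return filtfilt(b, a, x)


def preprocess_trial(trial: CopTrial, cutoff: float = DEFAULT_CUTOFF_HZ) -> CopTrial:
    """Return a copy of the trial with both axes low-pass filtered.

    No mean-centering is applied: the decomposition's residual absorbs any
    offset, so removing it here would double-handle the drift.
    """
    return CopTrial(
        subject_id=trial.subject_id,
        condition=trial.condition,
        trial_index=trial.trial_index,
        fs=trial.fs,
        cop_ap=lowpass_zero_phase(trial.cop_ap, trial.fs, cutoff),
        cop_ml=lowpass_zero_phase(trial.cop_ml, trial.fs, cutoff),
    )
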