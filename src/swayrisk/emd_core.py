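"""Empirical mode decomposition (EMD), implemented from scratch.

EMD decomposes a 1-D signal into intrinsic mode functions (IMFs) by iterative
*sifting*: the local mean, estimated as the average of cubic-spline envelopes
through the local maxima and minima, is subtracted until the candidate is a
well-formed oscillatory mode.  IMF1 carries the finest time scale; successive
IMFs are slower, and a monotone (or extrema-poor) residual terminates the
decomposition.

Design choices where the classical algorithm leaves freedom:

* Sift stopping rule: Huang's Cauchy criterion
  ``SD = sum((h_prev - h)**2) / sum(h_prev**2) < 0.2`` with a 100-iteration
  cap — strict enough for well-formed modes without over-sifting.
* Envelope boundary handling: two extrema are mirrored across each end of the
  record before spline fitting, the standard defense against end swings
  leaking into mode statistics.
* Plain EMD only; no ensemble or multivariate variants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = [
    "ImfSet",
    "InsufficientModesError",
    "find_extrema",
    "envelope",
    "sift_imf",
    "emd",
]

logger = logging.getLogger(__name__)

#: Cauchy sifting threshold and iteration cap.
SIFT_SD_THRESHOLD = 0.2
MAX_SIFT_ITERATIONS = 100

#: Number of extrema mirrored at each boundary before spline fitting.
N_MIRROR = 2

#: Minimum input length for a full decomposition.
MIN_EMD_SAMPLES = 256


class InsufficientModesError(RuntimeError):
    """Raised when fewer modes than required could be extracted."""

    def __init__(self, n_found: int, n_required: int):
        self.n_found = n_found
        self.n_required = n_required
        super().__init__(
            f"only {n_found} IMF(s) extracted, {n_required} required"
        )


@dataclass
class ImfSet:
    """Ordered IMFs plus residual for one signal (IMF1 = fastest mode)."""

    imfs: list[np.ndarray]
    residual: np.ndarray
    n_sift_iterations: list[int]
    source_len: int

    def __len__(self) -> int:
        return len(self.imfs)

    def imf(self, k: int) -> np.ndarray:
        """Return IMF ``k`` using the field's 1-based numbering."""
        if not 1 <= k <= len(self.imfs):
            raise IndexError(f"IMF index {k} out of range 1..{len(self.imfs)}")
        return self.imfs[k - 1]

    def reconstruct(self) -> np.ndarray:
        return np.sum(self.imfs, axis=0) + self.residual


def find_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict local maxima and minima.

    Interior plateaus of equal samples contribute the midpoint index of the
    run.  Fewer than two maxima or two minima signals a monotone residual to
    the caller (arrays are simply short); it is not an exception.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)

    # Collapse equal-valued runs so plateaus count once, at their midpoint.
    change = np.flatnonzero(np.diff(x) != 0)
    if change.size == 0:  # constant series
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    run_starts = np.concatenate(([0], change + 1))
    run_ends = np.concatenate((change, [len(x) - 1]))
    vals = x[run_starts]

    d = np.sign(np.diff(vals))
    interior = np.arange(1, len(vals) - 1)
    is_max = (d[interior - 1] > 0) & (d[interior] < 0)
    is_min = (d[interior - 1] < 0) & (d[interior] > 0)
    max_runs = interior[is_max]
    min_runs = interior[is_min]
    mid = (run_starts + run_ends) // 2
    return mid[max_runs], mid[min_runs]


def envelope(x: np.ndarray, extrema_idx: np.ndarray) -> np.ndarray:
    """Cubic-spline envelope through the given extrema, mirror-extended.

    Up to :data:`N_MIRROR` extrema are reflected across each end of the
    record (index 0 and index N-1) so the spline is anchored beyond the data
    and end swings are suppressed.
    """
    x = np.asarray(x, dtype=float)
    idx = np.asarray(extrema_idx, dtype=int)
    if idx.size < 2:
        raise ValueError("envelope needs at least 2 extrema")
    n = len(x)
    vals = x[idx]

    k = min(N_MIRROR, idx.size)
    left_t = -idx[:k][::-1].astype(float)
    left_v = vals[:k][::-1]
    right_t = (2 * (n - 1) - idx[-k:][::-1]).astype(float)
    right_v = vals[-k:][::-1]

    t = np.concatenate((left_t, idx.astype(float), right_t))
    v = np.concatenate((left_v, vals, right_v))
    # Mirroring an extremum sitting exactly on the boundary duplicates its
    # abscissa; keep the first occurrence.
    t, keep = np.unique(t, return_index=True)
    v = v[keep]
    spline = CubicSpline(t, v)
    return spline(np.arange(n, dtype=float))


def sift_imf(x: np.ndarray) -> tuple[np.ndarray, int]:
    """Extract one IMF from ``x`` by envelope-mean sifting.

    Iterates ``h <- h - (upper + lower)/2`` until the Cauchy criterion
    ``SD < 0.2`` is met *and* the candidate satisfies the mode condition
    (extrema and zero-crossing counts differing by at most one), or the
    iteration cap is reached (the cap is logged, never raised).
    """
    h = np.asarray(x, dtype=float).copy()
    n_iter = 0
    while n_iter < MAX_SIFT_ITERATIONS:
        max_idx, min_idx = find_extrema(h)
        if max_idx.size < 2 or min_idx.size < 2:
            break
        mean_env = 0.5 * (envelope(h, max_idx) + envelope(h, min_idx))
        h_new = h - mean_env
        n_iter += 1
        denom = np.sum(h * h)
        sd = np.sum((h - h_new) ** 2) / denom if denom > 0 else 0.0
        h = h_new
        if sd < SIFT_SD_THRESHOLD and _is_imf_shaped(h):
            break
    else:
        logger.debug("sift reached the %d-iteration cap", MAX_SIFT_ITERATIONS)
    return h, n_iter


def _is_imf_shaped(h: np.ndarray, slack: int = 1) -> bool:
    """Mode condition: extrema and zero-crossing counts differ by <= ``slack``."""
    max_idx, min_idx = find_extrema(h)
    zc = int(np.sum(np.diff(np.signbit(h)) != 0))
    return abs((max_idx.size + min_idx.size) - zc) <= slack


def emd(x: np.ndarray, max_imfs: int = 5, require: int | None = None) -> ImfSet:
    """Decompose ``x`` into up to ``max_imfs`` IMFs plus residual.

    Extraction stops early when the running residual is monotone or
    extrema-poor.  ``require`` (default: ``max_imfs``) sets the minimum
    number of modes; fewer raises :class:`InsufficientModesError`, because
    the feature stage needs a fixed mode count.  The residual is defined as
    ``x - sum(imfs)``, so reconstruction is exact up to float error.

    Pass ``require=0`` to accept however many modes exist.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < MIN_EMD_SAMPLES:
        raise ValueError(f"signal too short for EMD: {len(x)} < {MIN_EMD_SAMPLES}")
    if require is None:
        require = max_imfs

    imfs: list[np.ndarray] = []
    n_iters: list[int] = []
    residual = x.copy()
    for _ in range(max_imfs):
        max_idx, min_idx = find_extrema(residual)
        if max_idx.size < 2 or min_idx.size < 2:
            break
        imf, n_iter = sift_imf(residual)
        # A degenerate sift (no oscillation isolated) would loop forever.
        if not np.any(imf):
            break
        imfs.append(imf)
        n_iters.append(n_iter)
        residual = residual - imf

    if len(imfs) < require:
        raise InsufficientModesError(len(imfs), require)
    return ImfSet(
        imfs=imfs,
        residual=x - (np.sum(imfs, axis=0) if imfs else 0.0),
        n_sift_iterations=n_iters,
        source_len=len(x),
    )


def orthogonality_index(x: np.ndarray, imf_set: ImfSet) -> float:
    """Index of approximate orthogonality between extracted modes.

    ``IO = |sum_t sum_{j != k} imf_j(t) imf_k(t)| / sum_t x(t)^2``; small
    values indicate the modes carry distinct oscillatory content.  Reported
    for diagnostics; EMD does not guarantee exact orthogonality.
    """
    x = np.asarray(x, dtype=float)
    comps = imf_set.imfs
    total = np.sum(x * x)
    if total == 0:
        return 0.0
    s = np.sum(np.sum(comps, axis=0) ** 2) - sum(np.sum(c * c) for c in comps)
    return abs(s) / total
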