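"""Trial-level feature extraction from IMF series.

Thirteen metrics spanning five domains are computed on each of the first five
IMFs of each COP axis, giving a 130-dimensional named feature vector per
trial.  Names follow ``COP{ap|ml}_IMF{1..5}_{Metric}`` — e.g.
``COPap_IMF3_CV`` is the coefficient of variation of the third AP-axis IMF.

Metric conventions (each deliberate, since Table-level reproducibility hangs
on them):

* ``STD`` uses the N-1 denominator; ``RMS`` is ``sqrt(mean(x^2))`` — on the
  near-zero-mean IMFs the two agree to several decimals.
* ``TotalPower`` is the mean squared amplitude ``(1/N) sum x^2``, which by
  Parseval equals the integral of the normalised periodogram.
* ``CV`` is ``100·STD/|Mean|``, guarded for near-zero-mean modes: when
  ``|Mean| <= 1e-12·RMS`` the denominator is floored and a degeneracy flag
  is counted.
* ``ApEn``/``SampEn`` use embedding dimension m=2, tolerance r=0.2·SD and
  the Chebyshev distance; ApEn includes self-matches, SampEn excludes them.
* ``Skew`` is the Fisher moment skewness; ``Kurt`` is *excess* kurtosis
  (normal -> 0).
* ``BinEntropy`` is the Shannon entropy (natural log) of a 10-bin
  equal-width histogram spanning the series' own [min, max].

Features are computed on unstandardized IMF series; z-scoring happens only
inside model training, never here.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy import stats as sps

from .emd_core import ImfSet, emd
from .signal_prep import CopTrial, preprocess_trial

__all__ = [
    "EntropyParams",
    "BinEntropySpec",
    "FeatureVector",
    "METRICS",
    "N_FEATURES",
    "feature_names",
    "basic_stats",
    "total_power",
    "cv",
    "apen",
    "sampen",
    "skew_kurt",
    "bin_entropy",
    "extract_features",
    "trial_features",
]

logger = logging.getLogger(__name__)

#: Metric names in canonical order.
METRICS = (
    "Mean", "STD", "RMS", "Min", "Max", "IQR", "TotalPower",
    "CV", "ApEn", "SampEn", "Skew", "Kurt", "BinEntropy",
)
AXES = ("ap", "ml")
N_IMFS = 5
N_FEATURES = len(AXES) * N_IMFS * len(METRICS)  # 130

#: Degeneracy flags raised during extraction (e.g. near-zero-mean CV).
degeneracy_counter: Counter[str] = Counter()


@dataclass
class EntropyParams:
    """ApEn/SampEn parameters: embedding dimension and tolerance fraction."""

    m: int = 2
    r: float = 0.2  # tolerance as a fraction of the series SD

    def __post_init__(self) -> None:
        if self.m < 1 or self.r <= 0:
            raise ValueError("require m >= 1 and r > 0")


@dataclass
class BinEntropySpec:
    """Histogram-entropy parameters: bin count over the series' own range."""

    n_bins: int = 10


@dataclass
class FeatureVector:
    """Named trial-level features with trial linkage."""

    values: dict[str, float]
    subject_id: str
    condition: str
    trial_index: int

    def __post_init__(self) -> None:
        expected = set(feature_names())
        if set(self.values) != expected:
            missing = expected - set(self.values)
            extra = set(self.values) - expected
            raise ValueError(
                f"feature vector malformed: {len(missing)} missing, {len(extra)} extra"
            )
        if not all(np.isfinite(v) for v in self.values.values()):
            bad = [k for k, v in self.values.items() if not np.isfinite(v)]
            raise ValueError(f"non-finite features: {bad[:5]}")


def feature_names(metrics: tuple[str, ...] = METRICS) -> list[str]:
    """All feature names in canonical (axis, imf, metric) order."""
    return [
        f"COP{axis}_IMF{k}_{metric}"
        for axis in AXES
        for k in range(1, N_IMFS + 1)
        for metric in metrics
    ]


# ---------------------------------------------------------------------------
# individual metrics
# ---------------------------------------------------------------------------

def basic_stats(x: np.ndarray) -> tuple[float, float, float, float, float, float]:
    """(Mean, STD, RMS, Min, Max, IQR) with N-1 STD and type-7 quantiles."""
    x = np.asarray(x, dtype=float)
    if len(x) < 4:
        raise ValueError("need at least 4 samples")
    if not np.isfinite(x).all():
        raise ValueError("non-finite input")
    q1, q3 = np.percentile(x, [25, 75])  # linear interpolation (type 7)
    return (
        float(np.mean(x)),
        float(np.std(x, ddof=1)),
        float(np.sqrt(np.mean(x * x))),
        float(np.min(x)),
        float(np.max(x)),
        float(q3 - q1),
    )


def total_power(x: np.ndarray) -> float:
    """Mean squared amplitude, Parseval-equivalent to the periodogram integral."""
    x = np.asarray(x, dtype=float)
    return float(np.mean(x * x))


def cv(x: np.ndarray) -> float:
    """Coefficient of variation in percent, ``100·STD/|Mean|``, guarded.

    IMFs are near-zero-mean by construction, so an unguarded CV can blow up;
    when |Mean| falls below ``1e-12·RMS`` the denominator is floored and the
    event counted in :data:`degeneracy_counter`.
    """
    x = np.asarray(x, dtype=float)
    sd = float(np.std(x, ddof=1))
    mean = abs(float(np.mean(x)))
    eps = 1e-12 * float(np.sqrt(np.mean(x * x)))
    if mean > eps:
        return 100.0 * sd / mean
    degeneracy_counter["cv_zero_mean"] += 1
    return 100.0 * sd / (mean + eps) if (mean + eps) > 0 else 0.0


@njit(cache=False)
def _entropy_counts(y: np.ndarray, m: int, r: float):  # pragma: no cover
    """Pair-counting kernel shared by ApEn and SampEn.

    For templates of length ``m`` and ``m+1`` starting at i = 0..N-m-1
    (N-m templates of each length, so SampEn's A and B are comparable),
    counts Chebyshev matches within ``r`` for every unordered pair, plus the
    per-template match counts ApEn needs.  Also returns per-template counts
    for length-m templates over the full range i = 0..N-m (ApEn's phi_m).
    """
    n = y.shape[0]
    nm = n - m  # number of (m+1)-templates and of SampEn m-templates
    b_total = 0
    a_total = 0
    c_m = np.zeros(n - m + 1, dtype=np.int64)    # ApEn, length-m templates
    c_m1 = np.zeros(nm, dtype=np.int64)          # ApEn, length-(m+1)
    for i in range(n - m + 1):
        for j in range(i + 1, n - m + 1):
            d = 0.0
            for k in range(m):
                t = abs(y[i + k] - y[j + k])
                if t > d:
                    d = t
            if d <= r:
                c_m[i] += 1
                c_m[j] += 1
                if i < nm and j < nm:
                    b_total += 1
                    t = abs(y[i + m] - y[j + m])
                    if max(d, t) <= r:
                        a_total += 1
                        c_m1[i] += 1
                        c_m1[j] += 1
            elif i < nm and j < nm:
                # d > r for the m-prefix implies no (m+1)-match either
                pass
    return b_total, a_total, c_m, c_m1


def _tolerance(x: np.ndarray, p: EntropyParams) -> float:
    return p.r * float(np.std(x, ddof=1))


def _apen_from_counts(n: int, m: int, c_m: np.ndarray, c_m1: np.ndarray) -> float:
    phi_m = np.mean(np.log((c_m + 1) / (n - m + 1)))
    phi_m1 = np.mean(np.log((c_m1 + 1) / (n - m)))
    return float(phi_m - phi_m1)


def _sampen_from_counts(b: int, a: int) -> float:
    if b == 0:
        degeneracy_counter["sampen_no_templates"] += 1
        return 0.0
    if a == 0:
        degeneracy_counter["sampen_no_m1_matches"] += 1
        return float(np.log(b) + np.log(10.0))
    return float(-np.log(a / b))


def apen(x: np.ndarray, p: EntropyParams | None = None) -> float:
    """Approximate entropy (self-matches included).

    ``ApEn = Phi_m - Phi_{m+1}`` where ``Phi_m`` is the mean log fraction of
    length-m templates within tolerance of each template.
    """
    p = p or EntropyParams()
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < p.m + 2:
        raise ValueError("series too short for ApEn")
    r = _tolerance(x, p)
    _, _, c_m, c_m1 = _entropy_counts(x, p.m, r)
    return _apen_from_counts(n, p.m, c_m, c_m1)  # self-matches via the +1


def sampen(x: np.ndarray, p: EntropyParams | None = None) -> float:
    """Sample entropy ``-ln(A/B)`` (self-matches excluded).

    When no (m+1)-template pair matches (A = 0) the value is capped at
    ``ln(B) + ln(10)`` rather than returning infinity, and the event is
    counted as a degeneracy.
    """
    p = p or EntropyParams()
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < p.m + 2:
        raise ValueError("series too short for SampEn")
    r = _tolerance(x, p)
    b, a, _, _ = _entropy_counts(x, p.m, r)
    return _sampen_from_counts(b, a)


def skew_kurt(x: np.ndarray) -> tuple[float, float]:
    """(Fisher moment skewness, excess kurtosis)."""
    x = np.asarray(x, dtype=float)
    if len(x) < 4:
        raise ValueError("need at least 4 samples")
    if np.std(x) == 0:
        raise ValueError("zero variance: skewness/kurtosis undefined")
    return float(sps.skew(x)), float(sps.kurtosis(x, fisher=True))


def bin_entropy(x: np.ndarray, spec: BinEntropySpec | None = None) -> float:
    """Shannon entropy (nats) of the amplitude histogram.

    Equal-width bins over the series' own [min, max]; ``p_i`` is the bin
    occupancy fraction and ``0·ln 0 := 0``.  A constant series has zero
    range and returns 0 with a degeneracy flag.
    """
    spec = spec or BinEntropySpec()
    x = np.asarray(x, dtype=float)
    if len(x) < spec.n_bins:
        raise ValueError(f"need at least {spec.n_bins} samples")
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi == lo:
        degeneracy_counter["bin_entropy_constant"] += 1
        return 0.0
    counts, _ = np.histogram(x, bins=spec.n_bins, range=(lo, hi))
    p = counts[counts > 0] / len(x)
    return float(-np.sum(p * np.log(p)))


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def _metrics_for_series(
    x: np.ndarray,
    metrics: tuple[str, ...],
    entropy: EntropyParams,
    bins: BinEntropySpec,
) -> dict[str, float]:
    out: dict[str, float] = {}
    want = set(metrics)
    if want & {"Mean", "STD", "RMS", "Min", "Max", "IQR"}:
        mean, std, rms, lo, hi, iqr = basic_stats(x)
        out.update(Mean=mean, STD=std, RMS=rms, Min=lo, Max=hi, IQR=iqr)
    if "TotalPower" in want:
        out["TotalPower"] = total_power(x)
    if "CV" in want:
        out["CV"] = cv(x)
    if want >= {"ApEn", "SampEn"}:
        # one pair-counting pass serves both entropies
        xx = np.asarray(x, dtype=float)
        r = _tolerance(xx, entropy)
        b, a, c_m, c_m1 = _entropy_counts(xx, entropy.m, r)
        out["ApEn"] = _apen_from_counts(len(xx), entropy.m, c_m, c_m1)
        out["SampEn"] = _sampen_from_counts(b, a)
    elif "ApEn" in want:
        out["ApEn"] = apen(x, entropy)
    elif "SampEn" in want:
        out["SampEn"] = sampen(x, entropy)
    if want & {"Skew", "Kurt"}:
        sk, ku = skew_kurt(x)
        out.update(Skew=sk, Kurt=ku)
    if "BinEntropy" in want:
        out["BinEntropy"] = bin_entropy(x, bins)
    return {m: out[m] for m in metrics}


def extract_features(
    trial: CopTrial,
    imf_ap: ImfSet,
    imf_ml: ImfSet,
    entropy: EntropyParams | None = None,
    bins: BinEntropySpec | None = None,
    metrics: tuple[str, ...] = METRICS,
) -> FeatureVector | dict[str, float]:
    """All 130 named features for one trial's pair of decompositions.

    With the full default ``metrics`` tuple a validated
    :class:`FeatureVector` is returned; a restricted ``metrics`` tuple
    (useful when only cheap statistics are needed) returns a plain dict.
    """
    entropy = entropy or EntropyParams()
    bins = bins or BinEntropySpec()
    for name, imf_set in (("ap", imf_ap), ("ml", imf_ml)):
        if len(imf_set) < N_IMFS:
            raise ValueError(
                f"trial {trial.trial_id}: {name} axis has {len(imf_set)} IMFs, "
                f"{N_IMFS} required"
            )
    values: dict[str, float] = {}
    for axis, imf_set in (("ap", imf_ap), ("ml", imf_ml)):
        for k in range(1, N_IMFS + 1):
            per = _metrics_for_series(imf_set.imf(k), metrics, entropy, bins)
            for metric, val in per.items():
                values[f"COP{axis}_IMF{k}_{metric}"] = val
    if metrics == METRICS:
        return FeatureVector(
            values=values,
            subject_id=trial.subject_id,
            condition=trial.condition,
            trial_index=trial.trial_index,
        )
    return values


def trial_features(
    trial: CopTrial,
    metrics: tuple[str, ...] = METRICS,
    entropy: EntropyParams | None = None,
    preprocess: bool = True,
) -> dict[str, float]:
    """Convenience: filter, decompose both axes, and extract features."""
    t = preprocess_trial(trial) if preprocess else trial
    imf_ap = emd(t.cop_ap, max_imfs=N_IMFS)
    imf_ml = emd(t.cop_ml, max_imfs=N_IMFS)
    out = extract_features(t, imf_ap, imf_ml, entropy=entropy, metrics=metrics)
    return out.values if isinstance(out, FeatureVector) else out


def cohort_feature_table(
    dataset,
    condition: str | None = None,
    metrics: tuple[str, ...] = METRICS,
    entropy: EntropyParams | None = None,
    preprocess: bool = True,
    on_insufficient: str = "skip",
):
    """Wide trial-level feature table for a cohort.

    One row per trial: subject_id, condition, trial_index, label plus one
    column per feature.  ``metrics`` can be restricted when only a subset
    of statistics is needed (the expensive entropies dominate runtime).

    A small fraction of stochastic records (well under 1% at the default
    30 s duration) does not support five modes; ``on_insufficient`` chooses
    between dropping such trials with a log entry (``"skip"``, default) and
    propagating the error (``"raise"``).
    """
    import pandas as pd

    from .emd_core import InsufficientModesError

    if on_insufficient not in ("skip", "raise"):
        raise ValueError("on_insufficient must be 'skip' or 'raise'")
    rows = []
    for trial in dataset.trials_for(condition):
        try:
            vals = trial_features(trial, metrics=metrics, entropy=entropy, preprocess=preprocess)
        except InsufficientModesError as exc:
            if on_insufficient == "raise":
                raise
            logger.warning("trial %s dropped: %s", trial.trial_id, exc)
            continue
        rows.append(
            {
                "subject_id": trial.subject_id,
                "condition": trial.condition,
                "trial_index": trial.trial_index,
                "label": dataset.label(trial.subject_id),
                **vals,
            }
        )
    return pd.DataFrame(rows)
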