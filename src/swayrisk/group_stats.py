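"""Subject-level univariate group comparison of trial features.

Every statistical inference treats the subject as the observational unit:
trial-level features are first averaged per subject within a condition, then
each of the 130 features is compared between the fall-risk and no-fall-risk
groups.  The test choice is gated on normality — Shapiro-Wilk per group at
alpha 0.05; Welch's t-test when both groups pass, otherwise a two-sided
Mann-Whitney U (exact when group sizes permit, else the tie-corrected normal
approximation).  No multiplicity correction is applied; reports state this.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupComparison",
    "subject_level_table",
    "compare_feature",
    "compare_all_features",
    "significant_features",
]

ALPHA_NORMALITY = 0.05
ALPHA_SIG = 0.05

META_COLS = ("subject_id", "condition", "trial_index", "label")


@dataclass
class GroupComparison:
    """One feature's between-group comparison result."""

    feature_name: str
    mean_risk: float
    sd_risk: float
    mean_norisk: float
    sd_norisk: float
    test_used: str  # "welch_t" | "mann_whitney_u"
    p_value: float
    degenerate: bool = False

    @property
    def stars(self) -> str:
        if self.p_value < 0.001:
            return "***"
        if self.p_value < 0.01:
            return "**"
        if self.p_value < 0.05:
            return "*"
        return ""

    def formatted(self, digits: int = 4) -> dict[str, str]:
        f = f"{{:.{digits}f}}"
        return {
            "feature": self.feature_name,
            "fall_risk": f"{f.format(self.mean_risk)} ± {f.format(self.sd_risk)}",
            "no_fall_risk": f"{f.format(self.mean_norisk)} ± {f.format(self.sd_norisk)}",
            "p_value": f.format(self.p_value) + self.stars,
            "test": self.test_used,
        }


def subject_level_table(features: pd.DataFrame, condition: str | None = None) -> pd.DataFrame:
    """Per-subject mean of each feature over that subject's trials.

    ``features`` is a wide trial table (one row per trial; feature columns
    plus subject_id/condition/trial_index/label).  Restricting to one
    condition first is the usual workflow; ``condition=None`` pools all rows.
    """
    df = features if condition is None else features[features["condition"] == condition]
    if condition is not None:
        missing = set(features["subject_id"]) - set(df["subject_id"])
        if missing:
            raise ValueError(
                f"subjects with no trials in condition {condition!r}: {sorted(missing)[:5]}"
            )
    if df.empty:
        raise ValueError(f"no trials in condition {condition!r}")
    feat_cols = [c for c in df.columns if c not in META_COLS]
    agg = df.groupby("subject_id", sort=True)[feat_cols].mean()
    labels = df.groupby("subject_id", sort=True)["label"].first()
    agg.insert(0, "label", labels)
    return agg.reset_index()


def compare_feature(
    x_risk: np.ndarray,
    x_norisk: np.ndarray,
    feature_name: str = "",
    alpha_norm: float = ALPHA_NORMALITY,
) -> GroupComparison:
    """Normality-gated two-sample comparison of one feature.

    Welch's t is used only when *both* groups pass Shapiro-Wilk at
    ``alpha_norm`` (per-group testing is the defensible reading for a
    two-sample design).  With zero variance in both groups the comparison is
    degenerate and p = 1 is returned with a flag.
    """
    x_risk = np.asarray(x_risk, dtype=float)
    x_norisk = np.asarray(x_norisk, dtype=float)
    if len(x_risk) < 3 or len(x_norisk) < 3:
        raise ValueError("need at least 3 values per group")

    if np.ptp(x_risk) == 0 and np.ptp(x_norisk) == 0 and x_risk[0] == x_norisk[0]:
        return GroupComparison(
            feature_name, float(x_risk.mean()), 0.0, float(x_norisk.mean()), 0.0,
            "welch_t", 1.0, degenerate=True,
        )

    both_normal = (
        sps.shapiro(x_risk).pvalue >= alpha_norm if np.ptp(x_risk) > 0 else False
    ) and (
        sps.shapiro(x_norisk).pvalue >= alpha_norm if np.ptp(x_norisk) > 0 else False
    )
    if both_normal:
        test = "welch_t"
        p = float(sps.ttest_ind(x_risk, x_norisk, equal_var=False).pvalue)
    else:
        test = "mann_whitney_u"
        # scipy's "auto" uses the exact null distribution for small,
        # tie-free samples (the 8-subject risk group), else the
        # tie-corrected normal approximation.
        p = float(
            sps.mannwhitneyu(x_risk, x_norisk, alternative="two-sided", method="auto").pvalue
        )
    return GroupComparison(
        feature_name,
        float(np.mean(x_risk)),
        float(np.std(x_risk, ddof=1)),
        float(np.mean(x_norisk)),
        float(np.std(x_norisk, ddof=1)),
        test,
        p,
    )


def compare_all_features(subject_table: pd.DataFrame) -> list[GroupComparison]:
    """Compare every feature column between groups on a subject-level table."""
    risk = subject_table[subject_table["label"] == "fall_risk"]
    norisk = subject_table[subject_table["label"] == "no_fall_risk"]
    feat_cols = [c for c in subject_table.columns if c not in ("subject_id", "label")]
    return [
        compare_feature(risk[c].to_numpy(), norisk[c].to_numpy(), feature_name=c)
        for c in feat_cols
    ]


def significant_features(
    comparisons: list[GroupComparison], alpha: float = ALPHA_SIG
) -> pd.DataFrame:
    """Features with p < alpha, ascending p, formatted mean ± SD with stars.

    No multiple-testing correction is applied; ``attrs['note']`` carries the
    statement so report writers surface it.
    """
    rows = [c.formatted() | {"p_numeric": c.p_value} for c in comparisons if c.p_value < alpha]
    rows.sort(key=lambda r: r["p_numeric"])
    df = pd.DataFrame(
        rows, columns=["feature", "fall_risk", "no_fall_risk", "p_value", "test", "p_numeric"]
    )
    df.attrs["note"] = "uncorrected p-values; no multiplicity adjustment applied"
    return df
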