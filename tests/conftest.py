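"""Shared fixtures: small cohorts, seeded feature banks, toy feature tables.

Expensive banks (EMD over many cohorts) are session-scoped so several tests
can share one computation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from swayrisk.features import cohort_feature_table
from swayrisk.group_stats import subject_level_table
from swayrisk.synthetic_cohort import CohortSpec, EffectSpec, generate_cohort

#: Cheap metric subset (no quadratic-time entropies) used by the seeded banks.
CHEAP_METRICS = ("Mean", "STD", "RMS", "Min", "Max", "IQR", "TotalPower",
                 "CV", "Skew", "Kurt", "BinEntropy")

#: The three features carrying the injected group effect (high band -> IMF1).
INFORMATIVE = ["COPap_IMF1_IQR", "COPap_IMF1_Kurt", "COPml_IMF1_STD"]

N_BANK_SEEDS = 20


@pytest.fixture(scope="session")
def small_cohort():
    """A compact full-structure cohort (2 conditions) for plumbing tests."""
    spec = CohortSpec(
        n_fall_risk=3, n_no_risk=6, conditions=("rs_eo", "rs_ec"),
        trials_per_condition=2, duration=10.0, seed=42,
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def effect_bank():
    """20 seeded default-effect rs_ec cohorts reduced to cheap feature tables.

    Returns a list of (trial_table, subject_table) pairs.  Shared by the
    effect-direction property and the end-to-end classifier recovery check.
    """
    bank = []
    for seed in range(N_BANK_SEEDS):
        spec = CohortSpec(conditions=("rs_ec",), seed=seed)
        ds = generate_cohort(spec)
        trial_tab = cohort_feature_table(ds, metrics=CHEAP_METRICS)
        bank.append((trial_tab, subject_level_table(trial_tab, "rs_ec")))
    return bank


@pytest.fixture(scope="session")
def null_auc_bank():
    """20 seeded no-effect cohorts at the study's 8 + 24 group sizes,
    reduced to cheap feature tables, for the chance-level-AUC property."""
    bank = []
    for seed in range(N_BANK_SEEDS):
        spec = CohortSpec(conditions=("rs_ec",), effect=EffectSpec.null(), seed=200 + seed)
        bank.append(cohort_feature_table(generate_cohort(spec), metrics=CHEAP_METRICS))
    return bank


@pytest.fixture(scope="session")
def null_bank():
    """20 seeded no-effect cohorts at the study's 8 + 24 group sizes with
    all 130 features, for the type-I calibration of the univariate screen.

    Small-sample test calibration is size-sensitive (the Shapiro gate has
    little power and the exact Mann-Whitney null is coarse below ~8 per
    group), so these cohorts keep the study's group sizes.
    """
    bank = []
    for seed in range(N_BANK_SEEDS):
        spec = CohortSpec(
            conditions=("rs_ec",), effect=EffectSpec.null(), seed=1000 + seed,
        )
        ds = generate_cohort(spec)
        bank.append(cohort_feature_table(ds))
    return bank


def make_toy_features(
    seed: int,
    n_pos: int = 6,
    n_neg: int = 12,
    n_informative: int = 3,
    n_noise: int = 7,
    effect: float = 1.5,
    trials: int = 3,
) -> pd.DataFrame:
    """Trial-level toy feature table: informative columns shift with label."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_pos + n_neg):
        at_risk = i < n_pos
        shift = effect if at_risk else 0.0
        for t in range(trials):
            row = {
                "subject_id": f"S{i:02d}",
                "condition": "rs_ec",
                "trial_index": t + 1,
                "label": "fall_risk" if at_risk else "no_fall_risk",
            }
            for j in range(n_informative):
                row[f"f{j:02d}"] = shift + rng.normal()
            for j in range(n_informative, n_informative + n_noise):
                row[f"f{j:02d}"] = rng.normal()
            rows.append(row)
    return pd.DataFrame(rows)


@pytest.fixture
def toy_features():
    return make_toy_features(seed=7)
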