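import math

import numpy as np
import pandas as pd
import pytest

from cyclemetry.config import ConditionTruth, GeneratorConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_truth():
    """One condition: flat 1% weekly rate with a single annual harmonic."""
    return ConditionTruth(
        code="cond_A", alpha_true=0.01, beta_true=0.0,
        gamma_true=(0.001, -0.0005),
        harmonics_true=((1, 0.002, math.pi / 4),))


@pytest.fixture
def tiny_config(tiny_truth):
    return GeneratorConfig(n_members=500, n_weeks=120, n_groups=3,
                           conditions=(tiny_truth,), holiday_dip=0.5,
                           sex_ratio=0.5, seed=7)


@pytest.fixture
def hand_panel():
    """Three members, one stratum, hand-enumerable claims.

    All members are female, age 12 (age group 1), enrolled weeks 0-9.
    Week 2 has two diagnoses, week 5 has three (one member twice).
    """
    members = pd.DataFrame({
        "member_id": [0, 1, 2],
        "sex": ["F", "F", "F"],
        "age_mid": [12.0, 12.0, 12.0],
        "enroll_start_week": [0, 0, 0],
        "enroll_end_week": [9, 9, 9],
    })
    claims = pd.DataFrame({
        "member_id": [0, 1, 2, 0, 0],
        "week": [2, 2, 5, 5, 5],
        "condition": ["X"] * 5,
    })
    return members, claims
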