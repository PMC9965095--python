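from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from frailtyscreen import GeneratorConfig, ScoringConfig, generate_cohort
from frailtyscreen.scoring import score_and_classify
from frailtyscreen.synthetic import target_cutoff_proportions


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    return GeneratorConfig(n_male=800, n_female=800, seed=20240917)


@pytest.fixture(scope="session")
def small_cohort(small_config) -> pd.DataFrame:
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def scored_small(small_config, small_cohort):
    """Small cohort scored with reference-population (target-marginal) cutoffs."""
    cfg = ScoringConfig(proportion_overrides=target_cutoff_proportions(small_config))
    return score_and_classify(small_cohort, config=cfg)


def make_flags(E, G, W, L, P, sex="male", weights=None) -> pd.DataFrame:
    """Assemble a component-flag table directly from 0/1 vectors."""
    E, G, W, L, P = (np.asarray(v, dtype=int) for v in (E, G, W, L, P))
    n = len(E)
    df = pd.DataFrame(
        {
            "id": [f"x{i}" for i in range(n)],
            "E": E, "G": G, "W": W, "L": L, "P": P,
        }
    )
    df["S"] = df[["E", "G", "W", "L", "P"]].sum(axis=1)
    df["frail"] = (df["S"] >= 3).astype(int)
    df["sex"] = sex
    df["age_group"] = "60-69"
    df["weight"] = 1.0 if weights is None else np.asarray(weights, dtype=float)
    return df


@pytest.fixture
def flags_factory():
    return make_flags
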