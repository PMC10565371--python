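import numpy as np
import pandas as pd
import pytest

from assocnet.config import (
    FixedEffects,
    ReactionNormCovariance,
    SimulationConfig,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_sim_config():
    return SimulationConfig(
        n_individuals=20,
        n_years=4,
        surveys_per_year=(8, 16),
        mean_surveys_per_year=12,
        seed=7,
        fixed_effects=FixedEffects(intercept=0.5, env=0.3),
        rn_covariance=ReactionNormCovariance(0.2, 0.05, 0.0),
    )


def random_encounter_table(rng, n_individuals=10, n_encounters=20, year=2000, month=6):
    """Random long-format encounter table; every encounter non-empty."""
    ids = [f"A{i}" for i in range(n_individuals)]
    rows = []
    for e in range(1, n_encounters + 1):
        size = rng.integers(1, max(2, n_individuals // 2) + 1)
        members = rng.choice(ids, size=size, replace=False)
        for ind in members:
            rows.append((e, e, year, month, 15, ind))
    return pd.DataFrame(
        rows,
        columns=["encounter_id", "survey_id", "year", "month", "day", "individual_id"],
    )


def brute_force_sri(table):
    """Independent pair-count oracle: dict apis keyed by frozenset pairs,
    plus per-individual encounter counts."""
    groups = [
        set(sub["individual_id"]) for _, sub in table.groupby("encounter_id")
    ]
    ids = sorted(set().union(*groups))
    n = {i: sum(i in g for g in groups) for i in ids}
    sri = {}
    for a in ids:
        for b in ids:
            if a >= b:
                continue
            x = sum((a in g) and (b in g) for g in groups)
            denom = n[a] + n[b] - x
            sri[(a, b)] = x / denom if denom > 0 else 0.0
    return ids, n, sri
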