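import numpy as np
import pandas as pd
import pytest

from roosoc.synthetic import OutcomeConfig, PopulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_world():
    """A compact 2-year society reused by several test modules."""
    cfg = PopulationConfig(
        n_females=40, arena=(350.0, 350.0), n_years=2, surveys_per_month=10,
        n_preferred_dyads=30, follow_prob=0.6, seed=2024,
    )
    return simulate_dataset(cfg, n_fixes_per_female=80)


@pytest.fixture(scope="session")
def small_grouped(small_world):
    from roosoc.grouping import group_observations

    return group_observations(small_world.observations)


def random_grouped_sessions(rng, n_females=8, n_sessions=20):
    """Random grouped observation table for oracle comparisons."""
    ids = [f"F{i}" for i in range(n_females)]
    rows = []
    for s in range(n_sessions):
        present = [f for f in ids if rng.random() < 0.6]
        for f in present:
            rows.append({
                "session_id": f"s{s:02d}",
                "date": pd.Timestamp(2010, 1 + s % 12, 1 + s % 27),
                "female_id": f,
                "group_id": int(rng.integers(0, max(1, len(present) // 2))),
            })
    return pd.DataFrame(rows)


def brute_force_hwi(grouped, a, b):
    """Independent tally-and-formula HWI oracle for one dyad."""
    x = y_a = y_b = y_ab = 0
    for _, sess in grouped.groupby("session_id"):
        sub = sess.drop_duplicates(subset="female_id").set_index("female_id")
        ina, inb = a in sub.index, b in sub.index
        if ina and inb:
            if sub.loc[a, "group_id"] == sub.loc[b, "group_id"]:
                x += 1
            else:
                y_ab += 1
        elif ina:
            y_a += 1
        elif inb:
            y_b += 1
    denom = x + y_ab + 0.5 * (y_a + y_b)
    return x / denom if denom else 0.0


def brute_force_hwig(h):
    """Direct evaluation of the gregariousness correction, dyad by dyad."""
    n = h.shape[0]
    strength = h.sum(axis=1)
    total = h.sum()
    g = np.zeros_like(h)
    for i in range(n):
        for j in range(n):
            if i != j and strength[i] > 0 and strength[j] > 0:
                g[i, j] = h[i, j] * total / (strength[i] * strength[j])
            elif i != j:
                g[i, j] = np.nan
    return g
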