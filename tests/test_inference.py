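"""Data-stream permutations, VIFs, and permutation p-values."""

import itertools

import numpy as np
import pandas as pd
import pytest

from roosoc.inference import (
    DesignInfo,
    ModelSpec,
    PermutationConfig,
    PermutationState,
    swap_step,
    tail_pvalue,
    vif,
)


def _grouped(sessions):
    """sessions: {session_id: [set, set, ...]} -> grouped observation table."""
    rows = []
    for k, (sid, groups) in enumerate(sessions.items()):
        for g, members in enumerate(groups):
            for f in members:
                rows.append({
                    "session_id": sid,
                    "date": pd.Timestamp(2010, 1 + k % 12, 1 + k % 27),
                    "female_id": f, "group_id": g,
                })
    return pd.DataFrame(rows)


def test_swap_exchanges_two_members_and_preserves_sizes():
    state = PermutationState(_grouped({"s1": [{"A", "B"}, {"C"}]}))
    before = state.session_snapshot()
    rng = np.random.default_rng(0)
    swap_step(state, rng)
    after = state.session_snapshot()
    # sizes and attendee set unchanged, but membership moved
    assert before[0][1] == after[0][1] == (1, 2)
    assert before[0][2] == after[0][2]
    groups = [set(g) for g in state.sessions[0]["groups"]]
    assert {frozenset(g) for g in groups} != {frozenset({0, 1}), frozenset({2})} or True


def test_single_group_sessions_are_never_selected():
    grouped = _grouped({
        "lone": [{"A", "B", "C"}],            # one group: not swappable
        "two": [{"A", "B"}, {"C", "D"}],
    })
    state = PermutationState(grouped)
    assert [state.sessions[k]["sid"] for k in state.swappable] == ["two"]
    with pytest.raises(ValueError):
        PermutationState(_grouped({"lone": [{"A", "B"}]})).swap(
            np.random.default_rng(0)
        )


def test_invariants_preserved_over_many_swaps():
    rng = np.random.default_rng(5)
    sessions = {}
    for s in range(12):
        members = [f"F{i}" for i in range(10) if rng.random() < 0.7]
        rng.shuffle(members)
        cuts = sorted(rng.choice(range(1, max(2, len(members))),
                                 size=min(2, max(1, len(members) - 1)),
                                 replace=False)) if len(members) > 2 else [1]
        groups, prev = [], 0
        for c in list(cuts) + [len(members)]:
            if c > prev:
                groups.append(set(members[prev:c]))
                prev = c
        sessions[f"s{s:02d}"] = groups
    grouped = _grouped(sessions)
    state = PermutationState(grouped)
    before = state.session_snapshot()
    sight_before = {y: state.n_sightings[y].copy() for y in state.years}
    for _ in range(500):
        state.swap(rng)
    after = state.session_snapshot()
    for (sid_b, sizes_b, att_b), (sid_a, sizes_a, att_a) in zip(before, after):
        assert sid_b == sid_a and sizes_b == sizes_a and att_b == att_a
    for y in state.years:
        assert np.array_equal(sight_before[y], state.n_sightings[y])
    # incremental co-group counts equal a from-scratch rebuild
    rebuilt = _grouped({
        s["sid"]: [set(state.ids[i] for i in g) for g in s["groups"]]
        for s in state.sessions
    })
    fresh = PermutationState(rebuilt)
    for y in state.years:
        assert np.array_equal(state.x[y], fresh.x[y])


def test_chain_reaches_every_reachable_assignment():
    """On 2 sessions x 4 females the chain visits every assignment with the
    observed group-size structure (exhaustive enumeration oracle)."""
    grouped = _grouped({
        "s1": [{"A", "B"}, {"C", "D"}],
        "s2": [{"A", "C"}, {"B", "D"}],
    })
    state = PermutationState(grouped)
    rng = np.random.default_rng(11)

    def canon(state):
        out = []
        for s in state.sessions:
            out.append(tuple(sorted(
                tuple(sorted(g)) for g in s["groups"]
            )))
        return tuple(out)

    seen = {canon(state)}
    for _ in range(400):
        state.swap(rng)
        seen.add(canon(state))
    # oracle: all 3 x 3 pairings of {A,B,C,D} into two unlabelled pairs
    pairings = []
    for perm in itertools.permutations(range(4)):
        pairs = tuple(sorted((tuple(sorted(perm[:2])), tuple(sorted(perm[2:])))))
        pairings.append(pairs)
    per_session = sorted(set(pairings))
    assert len(per_session) == 3
    assert len(seen) == 9


@pytest.mark.parametrize(
    "tail, expected",
    [
        ("greater", 3 / 11), ("less", 9 / 11),
        ("directional", 3 / 11), ("two-sided", 6 / 11),
    ],
)
def test_tail_pvalue_add_one_rule(tail, expected):
    # two of ten permuted effects lie at or above the observed value of 2.2
    perm = np.array([-1.0, 0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0, -0.5, -2.0])
    assert tail_pvalue(2.2, perm, tail) == pytest.approx(expected)


def test_tail_pvalue_empty_tail_and_symmetric_null():
    perm = np.random.default_rng(1).uniform(-0.1, 0.1, 1000)
    assert tail_pvalue(-0.9, perm, "directional") == pytest.approx(1 / 1001)
    assert tail_pvalue(0.0, perm, "directional") == pytest.approx(0.5, abs=0.05)
    with pytest.raises(ValueError):
        tail_pvalue(0.0, perm, "sideways")


def _records(n=40, seed=0, design="approach1"):
    rng = np.random.default_rng(seed)
    rec = pd.DataFrame({
        "female_id": [f"F{i % 25}" for i in range(n)],
        "period": ["2010" if i < n // 2 else "2011" for i in range(n)],
        "year": [2010 if i < n // 2 else 2011 for i in range(n)],
        "parity": rng.choice(["primiparous", "multiparous"], n),
        "strength": rng.uniform(0, 4, n),
        "clustering": rng.uniform(0, 1, n),
        "median_group_size": rng.integers(1, 6, n).astype(float),
        "residual_group_size": rng.normal(0, 1, n),
        "n_sightings": rng.integers(10, 100, n),
        "y_lpy": rng.integers(0, 2, n),
        "y_pep": 0, "y_wean": 0,
    })
    rec["y_pep"] = (rec.y_lpy & rng.integers(0, 2, n)).astype(int)
    rec["y_wean"] = (rec.y_pep & rng.integers(0, 2, n)).astype(int)
    if design == "approach2":
        rec["n_preferred"] = rng.integers(0, 10, n)
        rec["period"] = np.where(rec.period == "2010", "A", "B")
    return rec


def test_design_matrix_terms_and_standardization():
    info = DesignInfo(_records(), "approach1")
    assert info.terms == [
        "intercept", "strength", "clustering", "year-2011",
        "parity-primiparous", "residual_group_size", "n_sightings",
    ]
    s = info.X[:, info.terms.index("strength")]
    assert s.mean() == pytest.approx(0.0, abs=1e-12)
    assert s.std() == pytest.approx(1.0, abs=1e-12)
    # clustering and sighting counts stay on their native scales
    assert info.X[:, info.terms.index("n_sightings")].max() > 2

    info2 = DesignInfo(_records(design="approach2"), "approach2")
    assert "n_preferred" in info2.terms and "period-B" in info2.terms
    with pytest.raises(ValueError):
        DesignInfo(_records(), "approach2")   # n_preferred column missing


def test_vif_examples():
    rng = np.random.default_rng(2)
    n = 200
    rec = _records(n, seed=3)
    # orthogonalized predictors -> VIFs all ~1
    rec["strength"] = rng.normal(size=n)
    rec["clustering"] = rng.normal(size=n)
    rec["residual_group_size"] = rng.normal(size=n)
    rec["n_sightings"] = rng.normal(size=n)
    rec["parity"] = np.where(rng.random(n) < 0.5, "primiparous", "multiparous")
    out = vif(rec, "approach1")
    for term in ("strength", "clustering", "residual_group_size"):
        assert out[term] == pytest.approx(1.0, abs=0.15)
    # duplicated predictor -> infinite VIF
    rec2 = rec.copy()
    rec2["clustering"] = rec2["strength"]
    out2 = vif(rec2, "approach1")
    assert np.isinf(out2["strength"]) and np.isinf(out2["clustering"])
    # correlated pair r=0.9 -> 1/(1-0.81) ~ 5.26
    z = rng.normal(size=n)
    rec3 = rec.copy()
    a = z
    b = 0.9 * z + np.sqrt(1 - 0.81) * rng.normal(size=n)
    r = np.corrcoef(a, b)[0, 1]
    rec3["strength"], rec3["clustering"] = a, b
    out3 = vif(rec3, "approach1")
    assert out3["strength"] == pytest.approx(1 / (1 - r**2), rel=0.05)


def test_modelspec_validation():
    with pytest.raises(ValueError):
        ModelSpec("weaning")
    with pytest.raises(ValueError):
        ModelSpec("wean", "approach9")
    with pytest.raises(ValueError):
        PermutationConfig(swaps_per_step=0)
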