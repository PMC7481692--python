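"""The synthetic society generator: determinism, structure, stated effects."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from roosoc.synthetic import (
    OutcomeConfig,
    PopulationConfig,
    simulate_dataset,
    simulate_gps_fixes,
    simulate_population,
    simulate_reproduction,
    simulate_sessions,
)


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        PopulationConfig(n_females=0)
    with pytest.raises(ValueError):
        PopulationConfig(arena=(0.0, 100.0))
    with pytest.raises(ValueError):
        PopulationConfig(follow_prob=1.5)
    with pytest.raises(ValueError):
        PopulationConfig(n_females=4, n_preferred_dyads=10)   # > 6 possible dyads
    with pytest.raises(ValueError):
        OutcomeConfig(stage_hazards={"SPY": 1.2})


def test_population_deterministic_and_dyads_symmetric():
    cfg = PopulationConfig(n_females=30, n_preferred_dyads=10, seed=1)
    a, b = simulate_population(cfg), simulate_population(cfg)
    assert [(f.id, f.hr_center, f.preferred_partners) for f in a] == [
        (f.id, f.hr_center, f.preferred_partners) for f in b
    ]
    dyads = {tuple(sorted((f.id, p))) for f in a for p in f.preferred_partners}
    assert len(dyads) == 10
    by_id = {f.id: f for f in a}
    for x, y in dyads:
        assert y in by_id[x].preferred_partners and x in by_id[y].preferred_partners
    w, h = cfg.arena
    assert all(0 <= f.hr_center[0] <= w and 0 <= f.hr_center[1] <= h for f in a)


def test_sessions_deterministic_and_presence_prob_one():
    cfg = PopulationConfig(
        n_females=12, n_years=1, surveys_per_month=2, presence_prob=1.0,
        presence_shape=1e9, n_preferred_dyads=5, seed=5,
    )
    pop = simulate_population(cfg)
    obs = simulate_sessions(pop, cfg)
    assert obs.equals(simulate_sessions(pop, cfg))
    per_session = obs.groupby("session_id")["female_id"].nunique()
    assert (per_session == 12).all()
    assert per_session.size == 24


def test_spread_population_yields_mostly_singletons():
    # follow_prob 0, tiny ranges, huge arena: co-membership is negligible
    cfg = PopulationConfig(
        n_females=30, arena=(20000.0, 20000.0), hr_sd=5.0, n_preferred_dyads=0,
        follow_prob=0.0, n_years=1, surveys_per_month=6, seed=9,
    )
    obs = simulate_sessions(simulate_population(cfg), cfg)
    sizes = obs.groupby(["session_id", "group_id"]).size()
    assert (sizes == 1).mean() > 0.999


def test_shared_range_centre_always_cogrouped():
    cfg = PopulationConfig(
        n_females=2, arena=(100.0, 100.0), hr_sd=1.0, n_preferred_dyads=0,
        follow_prob=0.0, presence_prob=1.0, presence_shape=1e9,
        n_years=1, surveys_per_month=10, seed=3,
    )
    pop = simulate_population(cfg)
    pop[1].hr_center = pop[0].hr_center
    obs = simulate_sessions(pop, cfg)
    # positions are both N(c, 1): P(distance > 15 m) is negligible
    n_groups = obs.groupby("session_id")["group_id"].nunique()
    assert (n_groups == 1).all()


def test_follow_prob_drives_cogrouping_of_preferred_dyads():
    base = dict(n_females=30, arena=(2000.0, 2000.0), hr_sd=10.0,
                n_preferred_dyads=6, presence_prob=1.0, presence_shape=1e9,
                n_years=1, surveys_per_month=10, seed=4)
    cfg_hi = PopulationConfig(follow_prob=0.9, **base)
    pop = simulate_population(cfg_hi)
    obs = simulate_sessions(pop, cfg_hi)
    dyads = {tuple(sorted((f.id, p))) for f in pop for p in f.preferred_partners}
    grp = obs.set_index(["session_id", "female_id"])["group_id"]
    degree = {}
    for a, b in dyads:
        degree[a] = degree.get(a, 0) + 1
        degree[b] = degree.get(b, 0) + 1
    rates, isolated_rates = [], []
    for a, b in dyads:
        same = [
            grp[(s, a)] == grp[(s, b)]
            for s in obs["session_id"].unique()
        ]
        rates.append(np.mean(same))
        if degree[a] == 1 and degree[b] == 1:
            isolated_rates.append(np.mean(same))
    # a dyad whose members have no other preferred partner co-groups in ~90%
    # of joint sessions; overlapping dyads trade off (a female cannot join two
    # distant chains at once) but still sit far above the spatial baseline
    assert isolated_rates and min(isolated_rates) > 0.8
    assert np.mean(rates) > 0.5


def test_gps_fixes_count_seed_and_clt_mean():
    cfg = PopulationConfig(n_females=5, n_preferred_dyads=2, seed=8)
    pop = simulate_population(cfg)
    fx = simulate_gps_fixes(pop, n_fixes_per_female=500, seed=2, years=[2010])
    assert fx.groupby("female_id").size().eq(500).all()
    assert fx.equals(simulate_gps_fixes(pop, 500, seed=2, years=[2010]))
    for f in pop:
        sub = fx[fx.female_id == f.id]
        se = f.hr_sd / np.sqrt(500)
        assert abs(sub.x.mean() - f.hr_center[0]) < 5 * se
        assert abs(sub.y.mean() - f.hr_center[1]) < 5 * se


def _flat_metrics(pop, years):
    rows = []
    for f in pop:
        for y in years:
            rows.append({"female_id": f.id, "year": y, "strength": 0.0,
                         "clustering": 0.0, "median_group_size": 1.0,
                         "n_sightings": 50, "residual_group_size": 0.0,
                         "n_preferred": 0})
    return pd.DataFrame(rows)


def test_everyone_weans_with_zero_hazards_and_betas():
    cfg = PopulationConfig(n_females=20, n_years=1, n_preferred_dyads=10, seed=6)
    pop = simulate_population(cfg)
    for f in pop:
        f.first_breeding_year = 2000   # all multiparous breeders
    oc = OutcomeConfig(beta0=40.0, beta_strength=0.0, beta_clustering=0.0,
                       beta_pref=0.0, beta_groupsize=0.0, beta_parity=0.0,
                       year_effects=(0.0,), stage_hazards={})
    states, truth = simulate_reproduction(pop, _flat_metrics(pop, [2010]), oc,
                                          seed=1, years=[2010])
    assert truth.lpy.all() and truth.pep.all() and truth.wean.all()


def test_state_sequences_are_monotone_within_cohort():
    cfg = PopulationConfig(n_females=15, n_years=2, n_preferred_dyads=10, seed=10)
    pop = simulate_population(cfg)
    oc = OutcomeConfig()
    states, _ = simulate_reproduction(pop, _flat_metrics(pop, [2010, 2011]), oc,
                                      seed=3, years=[2010, 2011])
    order = {"NPY": 0, "SPY": 1, "MPY": 2, "LPY": 3}
    for _, sub in states.groupby("female_id"):
        sub = sub.sort_values(["year", "month"])
        pouch = [order[s.split("+")[0]] if s != "YAF" else 0 for s in sub.state]
        # within a cohort the pouch stage never skips forward by more than one
        diffs = np.diff(pouch)
        assert (diffs <= 1).all()


def test_parity_odds_ratio_matches_beta_parity():
    # weaning frequency ratio between primiparous and multiparous females
    # recovers exp(beta_parity) by Monte Carlo at equal covariates
    rng_years = [2010]
    cfg = PopulationConfig(n_females=400, n_years=1, seed=13)
    pop = simulate_population(cfg)
    for i, f in enumerate(pop):
        f.first_breeding_year = 2010 if i < 200 else 2000
    beta_parity = -3.758
    oc = OutcomeConfig(beta0=1.2, beta_strength=0.0, beta_clustering=0.0,
                       beta_pref=0.0, beta_groupsize=0.0,
                       beta_parity=beta_parity, year_effects=(0.0,),
                       stage_hazards={})
    _, truth = simulate_reproduction(pop, _flat_metrics(pop, rng_years), oc,
                                     seed=7, years=rng_years)
    p_multi = truth[truth.parity == "multiparous"].wean.mean()
    p_prim = truth[truth.parity == "primiparous"].wean.mean()
    expected_prim = expit(1.2 + beta_parity)
    assert p_multi == pytest.approx(expit(1.2), abs=0.06)
    assert p_prim == pytest.approx(expected_prim, abs=0.04)


def test_strength_effect_recoverable_by_simulation():
    # per-SD effect of -0.9: weaning odds at +1 SD strength vs mean differ by
    # about e^-0.9, estimated from weaning frequencies over many females
    cfg = PopulationConfig(n_females=500, n_years=1, seed=14)
    pop = simulate_population(cfg)
    for f in pop:
        f.first_breeding_year = 2000
    metrics = _flat_metrics(pop, [2010])
    metrics["strength"] = np.where(np.arange(len(metrics)) < 250, 0.0, 1.0)
    oc = OutcomeConfig(beta0=0.2, beta_strength=-0.9, beta_clustering=0.0,
                       beta_pref=0.0, beta_groupsize=0.0, beta_parity=0.0,
                       year_effects=(0.0,), stage_hazards={})
    _, truth = simulate_reproduction(pop, metrics, oc, seed=9, years=[2010])
    merged = truth.merge(metrics, on=["female_id", "year"])
    z = (merged.strength - merged.strength.mean()) / merged.strength.std()
    lo = merged[z < 0].wean.mean()
    hi = merged[z > 0].wean.mean()
    log_or = np.log(hi / (1 - hi)) - np.log(lo / (1 - lo))
    # the two strength levels sit one SD apart (z = -1 and +1 gives 2 SD...)
    sd_gap = z.max() - z.min()
    assert log_or / sd_gap == pytest.approx(-0.9, abs=0.25)


def test_dataset_bundle_and_ground_truth_json(small_world):
    assert len(small_world.preferred_dyads) == 30
    payload = small_world.ground_truth_json()
    assert '"beta_strength"' in payload and '"outcomes"' in payload
    obs = small_world.observations
    assert {"session_id", "date", "female_id", "group_id", "x", "y",
            "state", "suckling"} <= set(obs.columns)
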