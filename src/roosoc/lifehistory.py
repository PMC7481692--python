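"""Reproductive-state sequences to annual outcomes and parity labels.

Field observers record each sighted female in one of six categories — NPY (no
pouch young), SPY/MPY/LPY (small/medium/large pouch young), YAF (young at
foot), SPY+YAF — plus a suckling flag on nursing young-at-foot evidence. This
module reconstructs young "episodes" from those sequences and derives, per
female and year: whether a young survived to the LPY stage, to permanent pouch
exit (PEP, marked by the first young-at-foot record), and to weaning. A young
counts as weaned eight months after its recorded PEP month unless suckling is
observed after that deadline; observed post-deadline suckling marks the young
as not weaned for that cohort.

All three outcomes of one young are anchored to the calendar year in which it
reaches LPY (inferred from the month before first YAF evidence when the LPY
stage itself was missed), which keeps the row invariant wean => PEP => LPY
even when later stages straddle a year boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

POUCH_ORDER = {"NPY": 0, "SPY": 1, "MPY": 2, "LPY": 3}
# rough months-since-birth offset of the first month of each observable stage,
# used only to back-infer birth years for parity
STAGE_BIRTH_OFFSET = {"SPY": 1, "MPY": 5, "LPY": 9, "YAF": 11}
WEANING_MONTHS_AFTER_PEP = 8


@dataclass
class Episode:
    """One young's observed trajectory."""

    stages: set = field(default_factory=set)
    first_month: dict = field(default_factory=dict)   # stage -> abs month index
    pep_month: int | None = None                      # first YAF evidence
    suckling_months: list = field(default_factory=list)
    flags: list = field(default_factory=list)

    @property
    def reached_lpy(self) -> bool:
        return "LPY" in self.stages or self.pep_month is not None

    def anchor_month(self) -> int | None:
        """Abs month anchoring the cohort year (first LPY, or month before PEP)."""
        if "LPY" in self.first_month:
            return self.first_month["LPY"]
        if self.pep_month is not None:
            return self.pep_month - 1
        if self.first_month:
            return max(self.first_month.values())
        return None

    def weaned(self) -> bool:
        if self.pep_month is None:
            return False
        deadline = self.pep_month + WEANING_MONTHS_AFTER_PEP
        return not any(m > deadline for m in self.suckling_months)


def _decompose(state: str) -> tuple[str, bool]:
    """Split a recorded category into (pouch stage, young-at-foot present)."""
    s = str(state).strip().upper().replace(" ", "")
    if s in ("SPY+YAF", "SPY,YAF", "SPYYAF"):
        return "SPY", True
    if s == "YAF":
        return "NPY", True
    if s in POUCH_ORDER:
        return s, False
    raise ValueError(f"unknown reproductive state {state!r}")


def monthly_states(records: pd.DataFrame) -> pd.DataFrame:
    """Collapse one female's records to one row per calendar month.

    Conflicting same-month states resolve to the most advanced pouch stage;
    young-at-foot and suckling evidence is OR-ed.
    """
    if "date" in records:
        d = pd.to_datetime(records["date"])
        abs_month = (d.dt.year * 12 + d.dt.month - 1).to_numpy(int)
    else:
        abs_month = (records["year"] * 12 + records["month"] - 1).to_numpy(int)
    state_codes, uniq_states = pd.factorize(records["state"])
    parts = [_decompose(s) for s in uniq_states]
    pouch = np.array([POUCH_ORDER[p] for p, _ in parts])[state_codes]
    yaf = np.array([y for _, y in parts])[state_codes]
    if "suckling" in records:
        suck = records["suckling"].fillna(False).to_numpy(bool)
    else:
        suck = np.zeros(len(records), bool)
    months, inverse = np.unique(abs_month, return_inverse=True)
    pouch_max = np.zeros(len(months), int)
    np.maximum.at(pouch_max, inverse, pouch)
    yaf_any = np.zeros(len(months), int)
    np.maximum.at(yaf_any, inverse, yaf.astype(int))
    suck_any = np.zeros(len(months), int)
    np.maximum.at(suck_any, inverse, suck.astype(int))
    inv = {v: k for k, v in POUCH_ORDER.items()}
    return pd.DataFrame({
        "abs_month": months,
        "pouch": [inv[v] for v in pouch_max],
        "yaf": yaf_any.astype(bool),
        "suckling": suck_any.astype(bool),
    })


# nursing evidence more than this many months after a young's PEP cannot
# belong to that young (weaning is ~8 months post-PEP; loss follows soon after
# a failed weaning), so later young-at-foot evidence signals the next cohort
MAX_NURSING_MONTHS_AFTER_PEP = WEANING_MONTHS_AFTER_PEP + 2
# a pouch exit must follow the last LPY sighting within this many months for
# young-at-foot evidence to be attributed to that pouch young
MAX_MONTHS_LPY_TO_EXIT = 4


def parse_episodes(records: pd.DataFrame) -> list[Episode]:
    """Reconstruct young episodes from one female's state records.

    A new pouch episode opens on the first pouch-young record, or when the
    observed stage regresses (a smaller young implies a new birth). Young-at
    -foot evidence (a YAF-bearing category, or a suckling flag) belongs to the
    open nursing episode while that young's nursing is still plausible; later
    evidence marks a pouch exit and attaches to the most recent pouch episode
    that displayed LPY within the previous four months (pouch exit follows the
    LPY stage). Evidence with neither an open nursing episode nor a fresh LPY
    candidate opens a standalone episode (a young first seen at foot, e.g. at
    a female's first sighting).
    """
    monthly = monthly_states(records)
    episodes: list[Episode] = []
    pouch_ep: Episode | None = None
    pouch_last: tuple[int, int] | None = None   # (stage rank, abs month)
    candidate: Episode | None = None            # last episode seen at LPY
    candidate_last: int = -10**9                # its last LPY sighting month
    yaf_ep: Episode | None = None
    for row in monthly.itertuples(index=False):
        m, stage, has_yaf, suck = row.abs_month, row.pouch, row.yaf, row.suckling
        rank = POUCH_ORDER[stage]
        if rank > 0:
            if pouch_ep is None or (pouch_last and rank < pouch_last[0]):
                pouch_ep = Episode()
                episodes.append(pouch_ep)
            pouch_ep.stages.add(stage)
            pouch_ep.first_month.setdefault(stage, m)
            pouch_last = (rank, m)
            if stage == "LPY":
                candidate, candidate_last = pouch_ep, m
        elif pouch_ep is not None and pouch_last and m - pouch_last[1] > 4:
            pouch_ep = None     # long NPY stretch: pouch young gone either way
        if yaf_ep is not None and m - yaf_ep.pep_month > MAX_NURSING_MONTHS_AFTER_PEP:
            yaf_ep = None       # that young's nursing cannot plausibly continue
        if has_yaf and yaf_ep is None:
            if (
                candidate is not None
                and candidate.pep_month is None
                and m - candidate_last <= MAX_MONTHS_LPY_TO_EXIT
            ):
                yaf_ep = candidate
                if pouch_ep is candidate:
                    pouch_ep, pouch_last = None, None   # it left the pouch
                candidate = None
            else:
                yaf_ep = Episode()
                yaf_ep.flags.append("young-first-seen-at-foot")
                episodes.append(yaf_ep)
            yaf_ep.stages.add("YAF")
            yaf_ep.pep_month = m
        if suck and yaf_ep is not None:
            yaf_ep.suckling_months.append(m)
    return episodes


def derive_outcomes(
    records: pd.DataFrame, year: int, episodes: list[Episode] | None = None
) -> tuple[bool, bool, bool]:
    """(lpy, pep, wean) for the cohort of ``year`` from one female's records.

    ``records`` must be the female's state records (date-sortable). Several
    episodes anchored to one year are combined by taking the most successful
    (the protocol produces at most one young per female-year). ``episodes``
    may carry a pre-parsed episode list to avoid re-parsing.
    """
    lpy = pep = wean = False
    for ep in (episodes if episodes is not None else parse_episodes(records)):
        am = ep.anchor_month()
        if am is None or am // 12 != year:
            continue
        lpy = lpy or ep.reached_lpy
        pep = pep or ep.pep_month is not None
        wean = wean or (ep.pep_month is not None and ep.weaned())
    # monotonicity is structural: weaning implies a PEP month, PEP implies LPY
    return lpy, pep, wean


def _birth_year_estimates(records, episodes: list[Episode] | None = None) -> list[int]:
    out = []
    for ep in (episodes if episodes is not None else parse_episodes(records)):
        if not ep.first_month and ep.pep_month is None:
            continue
        if ep.first_month:
            stage = min(ep.first_month, key=lambda s: POUCH_ORDER.get(s, 9))
            birth = ep.first_month[stage] - STAGE_BIRTH_OFFSET[stage]
        else:
            birth = ep.pep_month - STAGE_BIRTH_OFFSET["YAF"]
        out.append(birth // 12)
    return sorted(out)


def derive_parity(
    records: pd.DataFrame, year: int, episodes: list[Episode] | None = None
) -> str:
    """Parity label for one female in ``year``.

    'multiparous' with any inferred birth before ``year``; 'primiparous' when
    ``year`` holds her first recorded breeding (or she has never bred) and her
    observation history starts early enough to have caught an earlier breeding;
    otherwise 'unknown' (prior history censored).
    """
    births = _birth_year_estimates(records, episodes)
    if any(b < year for b in births):
        return "multiparous"
    d = pd.to_datetime(records["date"]) if "date" in records else None
    first_obs_year = int(d.dt.year.min()) if d is not None else int(records["year"].min())
    if first_obs_year < year:
        return "primiparous"
    return "unknown"


def build_records(
    observations: pd.DataFrame,
    metrics: pd.DataFrame,
    periods,
    design: str = "approach1",
) -> pd.DataFrame:
    """Model-ready rows: one per eligible female-period.

    ``metrics`` must already be restricted to eligible females (one row per
    female-period, from :func:`roosoc.metrics.metrics_table`). Outcomes come
    from the period's response year (the single year, or the second year of a
    2-year window, so no young is counted in two windows); rows with unknown
    parity are dropped.
    """
    if metrics.empty or observations.empty:
        return pd.DataFrame(
            columns=["female_id", "period", "year", "y_lpy", "y_pep", "y_wean",
                     "parity", "n_sightings", "strength", "clustering",
                     "median_group_size", "residual_group_size"]
        )
    by_female = dict(tuple(observations.groupby("female_id", observed=True)))
    episode_cache = {f: parse_episodes(obs) for f, obs in by_female.items()}
    period_map = {p.label: p for p in periods}
    rows = []
    for rec in metrics.itertuples(index=False):
        period = period_map[rec.period]
        year = period.response_year
        fobs = by_female.get(rec.female_id)
        if fobs is None:
            continue
        eps = episode_cache[rec.female_id]
        lpy, pep, wean = derive_outcomes(fobs, year, eps)
        parity = derive_parity(fobs, year, eps)
        if parity == "unknown":
            continue
        row = {
            "female_id": rec.female_id, "period": rec.period, "year": year,
            "y_lpy": int(lpy), "y_pep": int(pep), "y_wean": int(wean),
            "parity": parity, "n_sightings": rec.n_sightings,
            "strength": rec.strength, "clustering": rec.clustering,
            "median_group_size": rec.median_group_size,
            "residual_group_size": rec.residual_group_size,
        }
        if hasattr(rec, "n_preferred"):
            row["n_preferred"] = rec.n_preferred
        rows.append(row)
    out = pd.DataFrame(rows)
    if not out.empty:
        bad = out[(out.y_wean > out.y_pep) | (out.y_pep > out.y_lpy)]
        if len(bad):  # pragma: no cover - structural guarantee
            raise AssertionError("outcome monotonicity violated")
    return out
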