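"""Dyadic association indices for gambit-of-the-group survey data.

The half-weight index (HWI) for a dyad (a, b) over a set of survey sessions is

    HWI_ab = x / (x + y_ab + (y_a + y_b) / 2)

where x counts sessions with a and b in the same group, y_ab sessions with
both seen but in different groups, and y_a, y_b sessions with only one of the
two seen. With one sampling period per survey session this reduces to
2x / (n_a + n_b) with n_i the number of sessions individual i was seen in.

The gregariousness-corrected index (HWIG) rescales each dyad by its members'
overall sociability:

    HWIG_ab = HWI_ab * (sum_ij HWI_ij) / (sum_i HWI_ai * sum_j HWI_bj)

so that individual differences in overall association rate do not inflate
dyadic values; it is invariant under uniform rescaling of all HWIs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .periods import Period

logger = logging.getLogger(__name__)

MIN_SIGHTINGS = 10
MIN_GPS_FIXES = 50
MAX_STATE_GAP_MONTHS = 2


@dataclass(frozen=True)
class DyadCounts:
    """Session tallies underlying one dyad's association index."""

    x: int       # both seen, same group
    y_a: int     # only a seen
    y_b: int     # only b seen
    y_ab: int    # both seen, different groups

    def __post_init__(self) -> None:
        if min(self.x, self.y_a, self.y_b, self.y_ab) < 0:
            raise ValueError("dyad counts must be non-negative")


def hwi(c: DyadCounts) -> float:
    """Half-weight index from dyad counts; a never-seen dyad yields 0."""
    denom = c.x + c.y_ab + 0.5 * (c.y_a + c.y_b)
    if denom == 0:
        warnings.warn("all-zero dyad counts: never-seen dyad, HWI set to 0")
        return 0.0
    return c.x / denom


class AssociationMatrix:
    """Symmetric HWI matrix with its underlying co-sighting counts.

    Attributes
    ----------
    ids : list of female identifiers defining row/column order.
    x : (n, n) int array, sessions co-grouped.
    joint : (n, n) int array, sessions both present (any group).
    n_sightings : (n,) int array, sessions present.
    n_sessions : number of sessions in the period.
    """

    def __init__(self, ids, x, joint, n_sightings, n_sessions):
        self.ids = list(ids)
        self.x = np.asarray(x)
        self.joint = np.asarray(joint)
        self.n_sightings = np.asarray(n_sightings)
        self.n_sessions = int(n_sessions)
        self._index = {f: i for i, f in enumerate(self.ids)}

    def index(self, female_id) -> int:
        return self._index[female_id]

    @property
    def hwi(self) -> np.ndarray:
        return hwi_from_counts(self.x, self.n_sightings)

    def dyad_counts(self, a, b) -> DyadCounts:
        if a == b:
            raise ValueError("a dyad needs two distinct individuals")
        i, j = self._index[a], self._index[b]
        x = int(self.x[i, j])
        joint = int(self.joint[i, j])
        return DyadCounts(
            x=x,
            y_a=int(self.n_sightings[i]) - joint,
            y_b=int(self.n_sightings[j]) - joint,
            y_ab=joint - x,
        )

    def hwig(self) -> np.ndarray:
        return hwig_matrix(self.hwi)


def hwi_from_counts(x: np.ndarray, n_sightings: np.ndarray) -> np.ndarray:
    """Dense HWI matrix 2x / (n_i + n_j), zero diagonal and zero where undefined."""
    denom = n_sightings[:, None] + n_sightings[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        h = np.where(denom > 0, 2.0 * x / np.where(denom > 0, denom, 1), 0.0)
    np.fill_diagonal(h, 0.0)
    return h


def hwig_matrix(h: np.ndarray) -> np.ndarray:
    """Gregariousness-corrected association index (HWIG) from an HWI matrix.

    Dyads involving a zero-strength individual are undefined and returned as
    NaN; downstream consumers exclude them.
    """
    h = np.asarray(h, dtype=float)
    if h.shape[0] != h.shape[1] or not np.allclose(h, h.T):
        raise ValueError("HWI matrix must be square and symmetric")
    strength = h.sum(axis=1)
    total = strength.sum()
    if total == 0:
        raise ValueError("HWIG undefined: all associations are zero")
    zero = strength == 0
    if zero.any():
        logger.info("HWIG: %d zero-strength individuals flagged undefined", zero.sum())
    denom = np.outer(strength, strength)
    with np.errstate(invalid="ignore", divide="ignore"):
        g = h * total / denom
    g[zero, :] = np.nan
    g[:, zero] = np.nan
    np.fill_diagonal(g, 0.0)
    return g


def association_matrix(grouped: pd.DataFrame, ids=None) -> AssociationMatrix:
    """Build the HWI association matrix from grouped observations.

    Parameters
    ----------
    grouped
        Observation table with session_id, group_id, female_id columns
        (typically one analysis period's sessions). Duplicate female records
        within a session are counted once.
    ids
        Optional explicit female ordering; defaults to sorted observed ids.
    """
    from scipy import sparse

    g = grouped.drop_duplicates(subset=["session_id", "female_id"])
    if ids is None:
        ids = sorted(g["female_id"].unique().tolist())
    index = {f: i for i, f in enumerate(ids)}
    n = len(ids)
    n_sessions = int(g["session_id"].nunique())
    fem = g["female_id"].map(index)
    keep = fem.notna().to_numpy()
    fem = fem.to_numpy(object)[keep].astype(int)
    sess_codes = pd.factorize(g["session_id"])[0][keep]
    grp_codes = pd.factorize(
        pd.MultiIndex.from_arrays([g["session_id"], g["group_id"]])[keep]
    )[0]
    if len(fem) == 0:
        zero = np.zeros((n, n), dtype=np.int64)
        return AssociationMatrix(ids, zero, zero.copy(), np.zeros(n, int), n_sessions)
    ones = np.ones(len(fem), dtype=np.int64)
    # sessions-both-present and sessions-co-grouped as sparse cross products
    P = sparse.csr_matrix((ones, (sess_codes, fem)), shape=(sess_codes.max() + 1, n))
    G = sparse.csr_matrix((ones, (grp_codes, fem)), shape=(grp_codes.max() + 1, n))
    joint = np.asarray((P.T @ P).todense(), dtype=np.int64)
    x = np.asarray((G.T @ G).todense(), dtype=np.int64)
    n_sight = np.diag(joint).copy()
    np.fill_diagonal(x, 0)
    np.fill_diagonal(joint, 0)
    return AssociationMatrix(ids, x, joint, n_sight, n_sessions)


def dyad_counts(grouped: pd.DataFrame, a, b) -> DyadCounts:
    """Exact dyad tallies over all sessions of a grouped observation table."""
    if a == b:
        raise ValueError("a dyad needs two distinct individuals")
    g = grouped.drop_duplicates(subset=["session_id", "female_id"])
    x = y_a = y_b = y_ab = 0
    for _, sess in g.groupby("session_id", sort=False):
        rows = sess[sess["female_id"].isin([a, b])]
        seen = set(rows["female_id"])
        if seen == {a, b}:
            if rows.set_index("female_id")["group_id"].nunique() == 1:
                x += 1
            else:
                y_ab += 1
        elif seen == {a}:
            y_a += 1
        elif seen == {b}:
            y_b += 1
    return DyadCounts(x=x, y_a=y_a, y_b=y_b, y_ab=y_ab)


def _month_coverage_ok(months: np.ndarray, year: int, max_gap: int) -> bool:
    """Bimonthly reproductive-state coverage within one calendar year.

    No gap between consecutive records may exceed ``max_gap`` calendar months,
    and records must reach both year edges (first by month 1+max_gap-1, last by
    month 12-max_gap+1) so that no milestone window can fall wholly between
    records.
    """
    m = np.sort(np.unique(months))
    if len(m) == 0:
        return False
    if m[0] > max_gap or m[-1] < 13 - max_gap:
        return False
    return len(m) == 1 or int(np.max(np.diff(m))) <= max_gap


def filter_eligible(
    observations: pd.DataFrame,
    gps_fixes: pd.DataFrame | None,
    design: str,
    period: Period,
    min_sightings: int = MIN_SIGHTINGS,
    min_fixes: int = MIN_GPS_FIXES,
    max_gap_months: int = MAX_STATE_GAP_MONTHS,
) -> set:
    """Females meeting the inclusion criteria of a design for one period.

    approach1 (single years): at least ``min_sightings`` survey sightings in
    the year and reproductive-state records at least every ``max_gap_months``
    calendar months. approach2 (2-year windows): at least ``min_sightings``
    sightings and at least ``min_fixes`` GPS fixes within the window.
    """
    if design not in ("approach1", "approach2"):
        raise ValueError(f"unknown design {design!r}")
    obs = observations.copy()
    dates = pd.to_datetime(obs["date"])
    obs = obs[dates.dt.year.isin(period.years)]
    dates = pd.to_datetime(obs["date"])
    dedup = obs.assign(_month=dates.dt.month, _year=dates.dt.year).drop_duplicates(
        subset=["session_id", "female_id"]
    )
    counts = dedup.groupby("female_id", observed=True).size()
    eligible = set(counts[counts >= min_sightings].index)
    if design == "approach1":
        year = period.years[0]
        keep = set()
        for fid in eligible:
            months = dedup.loc[
                (dedup["female_id"] == fid) & (dedup["_year"] == year), "_month"
            ].to_numpy()
            if _month_coverage_ok(months, year, max_gap_months):
                keep.add(fid)
        return keep
    if gps_fixes is None or gps_fixes.empty:
        return set()
    fx = gps_fixes[pd.to_datetime(gps_fixes["date"]).dt.year.isin(period.years)]
    fix_counts = fx.groupby("female_id", observed=True).size()
    enough_fixes = set(fix_counts[fix_counts >= min_fixes].index)
    return eligible & enough_fixes
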