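"""Group assignment by the chain rule, and per-female group-size summaries.

A survey session is an instantaneous snapshot of individual positions. Group
membership follows the chain rule used for fission-fusion macropod societies:
two individuals belong to the same group if they are linked by a chain of
pairwise distances each no greater than the threshold (default 15 m). Groups
are therefore the connected components of the proximity graph; singletons are
valid groups. Distances are Euclidean on planar metre coordinates and a
distance of exactly 15.0 m counts as "within" the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

DEFAULT_CHAIN_THRESHOLD = 15.0


@dataclass
class SessionPositions:
    """Observed individual coordinates (metres) for one survey session."""

    session_id: str
    members: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for fid, (x, y) in self.members.items():
            if x is None or y is None or not (np.isfinite(x) and np.isfinite(y)):
                raise ValueError(
                    f"session {self.session_id!r}: missing or non-finite "
                    f"coordinates for individual {fid!r}"
                )


@dataclass
class GroupedSession:
    """A partition of one session's observed individuals into groups."""

    session_id: str
    groups: list[set[str]]

    def group_of(self, female_id: str) -> set[str]:
        for g in self.groups:
            if female_id in g:
                return g
        raise KeyError(female_id)


def chain_rule_labels(coords: np.ndarray, threshold: float = DEFAULT_CHAIN_THRESHOLD) -> np.ndarray:
    """Connected-component labels of the proximity graph over ``coords``.

    Parameters
    ----------
    coords
        Array of shape (n, 2), planar metre coordinates.
    threshold
        Chain distance in metres (closed: pairs exactly at the threshold link).

    Returns
    -------
    Integer label per row; equal labels mean same group.
    """
    if threshold <= 0:
        raise ValueError("chain threshold must be positive")
    n = len(coords)
    if n == 0:
        return np.empty(0, dtype=int)
    if n == 1:
        return np.zeros(1, dtype=int)
    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=threshold, output_type="ndarray")
    adj = sparse.coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
    )
    _, labels = connected_components(adj, directed=False)
    return labels


def assign_groups(
    positions: SessionPositions, threshold: float = DEFAULT_CHAIN_THRESHOLD
) -> GroupedSession:
    """Partition one session into groups by the chain rule."""
    ids = list(positions.members)
    coords = np.array([positions.members[i] for i in ids], dtype=float).reshape(-1, 2)
    labels = chain_rule_labels(coords, threshold)
    groups: dict[int, set[str]] = {}
    for fid, lab in zip(ids, labels):
        groups.setdefault(int(lab), set()).add(fid)
    return GroupedSession(positions.session_id, [groups[k] for k in sorted(groups)])


def group_observations(
    observations: pd.DataFrame, threshold: float = DEFAULT_CHAIN_THRESHOLD
) -> pd.DataFrame:
    """Assign a ``group_id`` within every session of an observation table.

    Uses per-member coordinates where available. Sessions without usable
    coordinates fall back to the recorded ``group_id`` column if present
    (field protocols sometimes record only a group-centre fix); sessions with
    neither raise.
    """
    out = []
    for sid, sess in observations.groupby("session_id", sort=True):
        sess = sess.drop_duplicates(subset="female_id")
        has_xy = (
            "x" in sess and "y" in sess
            and sess["x"].notna().all() and sess["y"].notna().all()
        )
        if has_xy:
            labels = chain_rule_labels(sess[["x", "y"]].to_numpy(float), threshold)
        elif "group_id" in sess and sess["group_id"].notna().all():
            labels = sess["group_id"].to_numpy()
        else:
            missing = sess.loc[sess.get("x", pd.Series(dtype=float)).isna(), "female_id"]
            raise ValueError(
                f"session {sid!r}: missing coordinates for "
                f"{sorted(map(str, missing)) if len(missing) else 'all members'}"
            )
        sess = sess.copy()
        sess["group_id"] = labels
        out.append(sess)
    return pd.concat(out, ignore_index=True) if out else observations.iloc[0:0].copy()


def group_sizes_by_female(grouped: pd.DataFrame) -> pd.DataFrame:
    """Long table (session_id, female_id, group_size) from grouped observations.

    Group sizes count adult/sub-adult females only; the observation table is
    female-only by construction, so the size is the number of rows sharing the
    session and group.
    """
    g = grouped.drop_duplicates(subset=["session_id", "female_id"]).copy()
    sizes = g.groupby(["session_id", "group_id"])["female_id"].transform("size")
    g["group_size"] = sizes
    return g[["session_id", "female_id", "group_size"]]


def median_group_size(grouped: pd.DataFrame, female_id: str, sessions: set[str] | None = None) -> float:
    """Median size of the groups in which a female was encountered.

    Even-length medians use the midpoint (mean of the central pair). Raises
    when the female has no sightings in the requested sessions.
    """
    tab = group_sizes_by_female(grouped)
    tab = tab[tab["female_id"] == female_id]
    if sessions is not None:
        tab = tab[tab["session_id"].isin(sessions)]
    if tab.empty:
        raise ValueError(f"female {female_id!r} has no sightings in the period")
    return float(np.median(tab["group_size"].to_numpy()))


def sighting_counts(observations: pd.DataFrame, sessions: set[str] | None = None) -> dict[str, int]:
    """Per-individual number of sessions in which she appears.

    Duplicate records of one female within a session (field double entry)
    count once.
    """
    obs = observations
    if sessions is not None:
        obs = obs[obs["session_id"].isin(sessions)]
    if obs.empty:
        return {}
    dedup = obs.drop_duplicates(subset=["session_id", "female_id"])
    return dedup.groupby("female_id", observed=True).size().to_dict()
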