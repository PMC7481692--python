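"""CSV dialects and network exports.

Observation tables are UTF-8 CSVs with ISO dates and metre coordinates:
required columns session_id, date, female_id; optional x, y, group_id, state,
suckling. GPS fix tables require female_id, date, x, y. Extra columns are
preserved verbatim on round trips. Association matrices export as wide CSV
and as GraphML with HWI edge weights.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

OBS_REQUIRED = ("session_id", "date", "female_id")
GPS_REQUIRED = ("female_id", "date", "x", "y")


def _validate(df: pd.DataFrame, required, what: str, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{what} {path}: missing required column(s) {missing}")
    for col in required:
        bad = df.index[df[col].isna()]
        if len(bad):
            raise ValueError(
                f"{what} {path}: column {col!r} has missing values at rows "
                f"{bad[:5].tolist()}{'...' if len(bad) > 5 else ''}"
            )


def read_observations(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _validate(df, OBS_REQUIRED, "observation table", path)
    df["date"] = pd.to_datetime(df["date"])
    if "suckling" in df:
        df["suckling"] = df["suckling"].astype(bool)
    return df


def write_observations(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, index=False)


def read_gps_fixes(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _validate(df, GPS_REQUIRED, "GPS fix table", path)
    df["date"] = pd.to_datetime(df["date"])
    return df


def write_gps_fixes(df: pd.DataFrame, path) -> None:
    write_observations(df, path)   # same dialect


def write_association_csv(matrix, path) -> None:
    """Wide CSV of the HWI matrix (ids as header and index)."""
    pd.DataFrame(matrix.hwi, index=matrix.ids, columns=matrix.ids).to_csv(path)


def association_graph(matrix) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(matrix.ids)
    h = matrix.hwi
    for i, a in enumerate(matrix.ids):
        for j in range(i + 1, len(matrix.ids)):
            if h[i, j] > 0:
                g.add_edge(a, matrix.ids[j], weight=float(h[i, j]))
    return g


def write_graphml(matrix, path) -> None:
    nx.write_graphml(association_graph(matrix), path)


def write_model_table(result, path) -> None:
    tab = result.table()
    tab.to_csv(Path(path).with_suffix(".csv"), index=False)
    payload = {
        "response": result.spec.response,
        "design": result.spec.design,
        "tail": result.tail,
        "random_intercept_variance": result.glmm.re_var,
        "n_obs": result.glmm.n_obs,
        "n_females": result.glmm.n_groups,
        "vif": {k: (None if np.isinf(v) else v) for k, v in result.vifs.items()},
        "terms": tab.replace({np.nan: None}).to_dict(orient="records"),
    }
    import json

    Path(path).with_suffix(".json").write_text(json.dumps(payload, indent=1))
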