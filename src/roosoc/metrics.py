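"""Per-female sociability covariates: strength, clustering, residual group size.

Strength is the weighted degree (row sum of the HWI matrix). The local
clustering coefficient is computed on the binarized association graph
(HWI > 0): the fraction of an individual's associate pairs that are
themselves associated; individuals with fewer than two associates get 0
(flagged, not missing, so their model rows survive).

Median group size is strongly collinear with strength, so the gregariousness
covariate entering the reproductive models is the conditional residual of a
linear mixed model

    median_group_size ~ strength + (1 | female)

i.e. observed minus fixed-effect prediction minus the female's predicted
random intercept. The mixed model is a profiled-REML random-intercept fit
written directly on group-level sufficient statistics so it is cheap enough
to re-fit inside data-stream permutation chains.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

logger = logging.getLogger(__name__)


def strength(matrix, female_id=None) -> np.ndarray | float:
    """Sum of association indices (row sum excluding the diagonal).

    With ``female_id`` given, returns that female's strength; otherwise the
    full vector in matrix order.
    """
    h = matrix.hwi if hasattr(matrix, "hwi") and not isinstance(matrix, np.ndarray) else np.asarray(matrix)
    h = np.asarray(h, dtype=float)
    s = h.sum(axis=1) - np.diag(h)
    if female_id is None:
        return s
    return float(s[matrix.index(female_id)])


def local_clustering(matrix, female_id=None) -> np.ndarray | float:
    """Binary local clustering coefficient over HWI > 0 edges.

    For individual i with degree d and adjacency A: number of linked
    neighbour pairs divided by d(d-1)/2; degree < 2 yields 0.
    """
    h = matrix.hwi if hasattr(matrix, "hwi") and not isinstance(matrix, np.ndarray) else np.asarray(matrix)
    a = (np.asarray(h) > 0).astype(float)
    np.fill_diagonal(a, 0.0)
    deg = a.sum(axis=1)
    # triangles through i = (A^3)_ii / 2
    tri = np.einsum("ij,jk,ki->i", a, a, a) / 2.0
    denom = deg * (deg - 1) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(denom > 0, tri / np.where(denom > 0, denom, 1), 0.0)
    if female_id is None:
        return c
    return float(c[matrix.index(female_id)])


@dataclass
class RandomInterceptLM:
    """Fitted random-intercept linear model y ~ X beta + u_g + e (REML)."""

    beta: np.ndarray
    var_u: float
    var_e: float
    group_labels: np.ndarray          # distinct group codes
    blup: np.ndarray                  # predicted random intercept per group
    method: str = "reml"

    def conditional_residuals(self, X, y, groups) -> np.ndarray:
        fitted = X @ self.beta
        u = pd.Series(self.blup, index=self.group_labels).reindex(groups).to_numpy()
        return y - fitted - np.nan_to_num(u)


def fit_random_intercept_lm(X, y, groups, reml: bool = True) -> RandomInterceptLM:
    """Profiled one-variance-component linear mixed model.

    Profiles the variance ratio lambda = var_u / var_e with group-level
    sufficient statistics, so each criterion evaluation is O(n). Degenerate
    designs (singular X, e.g. constant covariate) fall back to a pseudoinverse
    fixed-effects fit with lambda = 0, logged.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    n, p = X.shape
    if n < 2:
        raise ValueError("need at least 2 records")
    labels, gidx = np.unique(groups, return_inverse=True)
    ng = np.bincount(gidx).astype(float)

    def gls(lam: float):
        # (I + lam J)^-1 = I - (lam / (1 + n_g lam)) J within each group
        w = lam / (1.0 + ng * lam)             # per-group shrinkage
        gx = np.zeros((len(labels), p))
        np.add.at(gx, gidx, X)
        gy = np.bincount(gidx, weights=y)
        xtvx = X.T @ X - (gx * w[:, None]).T @ gx
        xtvy = X.T @ y - (gx * w[:, None]).T @ gy
        try:
            beta = np.linalg.solve(xtvx, xtvy)
        except np.linalg.LinAlgError:
            beta = np.linalg.pinv(xtvx) @ xtvy
        r = y - X @ beta
        gr = np.bincount(gidx, weights=r)
        quad = r @ r - w @ (gr * gr)
        return beta, xtvx, quad, w, gr

    def neg_criterion(log_lam: float) -> float:
        lam = np.exp(log_lam)
        beta, xtvx, quad, w, _ = gls(lam)
        dof = n - p if reml else n
        sigma2 = max(quad / dof, 1e-300)
        logdet_v = np.sum(np.log1p(ng * lam))
        ll = -0.5 * (dof * np.log(sigma2) + logdet_v + dof)
        if reml:
            sign, logdet_x = np.linalg.slogdet(xtvx)
            ll -= 0.5 * (logdet_x if sign > 0 else np.inf)
        return -ll

    singular = np.linalg.matrix_rank(X) < p
    if np.ptp(y) == 0:
        # constant response: exact fit, no variance components to estimate
        beta = np.linalg.pinv(X) @ y
        return RandomInterceptLM(beta, 0.0, 0.0, labels, np.zeros(len(labels)))
    if singular or len(labels) == n or len(labels) < 2:
        # unidentifiable variance ratio or singular design: plain (pseudo)OLS
        if singular:
            logger.warning("residual group size: degenerate design, using fixed-effects fallback")
        beta = np.linalg.pinv(X) @ y
        r = y - X @ beta
        var_e = float(r @ r / max(n - p, 1))
        return RandomInterceptLM(beta, 0.0, var_e, labels, np.zeros(len(labels)),
                                 method="ols-fallback" if singular else "reml")

    res = minimize_scalar(neg_criterion, bounds=(-12.0, 8.0), method="bounded",
                          options={"xatol": 1e-6})
    lam = float(np.exp(res.x))
    if neg_criterion(-30.0) <= res.fun:  # boundary: variance component at zero
        lam = 0.0
    beta, _, quad, w, gr = gls(lam)
    dof = n - p if reml else n
    var_e = float(quad / dof)
    var_u = lam * var_e
    # BLUP: u_g = lam/(1+n_g lam) * sum of marginal residuals in g
    blup = (lam / (1.0 + ng * lam)) * gr
    return RandomInterceptLM(beta, var_u, var_e, labels, blup)


def residual_group_size(records: pd.DataFrame) -> pd.Series:
    """Gregariousness covariate: conditional residuals of median group size on strength.

    ``records`` needs columns female_id, median_group_size, strength; one row
    per female-period. Returns residuals aligned to the input index.
    """
    if len(records) < 2:
        raise ValueError("need at least 2 records to regress group size on strength")
    X = np.column_stack([np.ones(len(records)), records["strength"].to_numpy(float)])
    y = records["median_group_size"].to_numpy(float)
    fit = fit_random_intercept_lm(X, y, records["female_id"].to_numpy())
    resid = fit.conditional_residuals(X, y, records["female_id"].to_numpy())
    return pd.Series(resid, index=records.index, name="residual_group_size")


def metrics_table(
    matrices: dict, grouped: pd.DataFrame, periods, session_periods: pd.Series
) -> pd.DataFrame:
    """One row per female-period with all sociability covariates.

    Parameters
    ----------
    matrices
        period label -> AssociationMatrix over that period's eligible females.
    grouped
        Grouped observation table (all sessions).
    periods
        list of Period.
    session_periods
        session_id -> set of period labels membership (precomputed by caller
        as a Series of lists).
    """
    from .grouping import group_sizes_by_female

    sizes = group_sizes_by_female(grouped)
    rows = []
    for period in periods:
        mat = matrices[period.label]
        s = strength(mat)
        c = local_clustering(mat)
        sess_in = {
            sid for sid, labs in session_periods.items() if period.label in labs
        }
        tab = sizes[sizes["session_id"].isin(sess_in)]
        med = tab.groupby("female_id", observed=True)["group_size"].median()
        for i, fid in enumerate(mat.ids):
            rows.append(
                {
                    "female_id": fid,
                    "period": period.label,
                    "strength": float(s[i]),
                    "clustering": float(c[i]),
                    "median_group_size": float(med.get(fid, np.nan)),
                    "n_sightings": int(mat.n_sightings[i]),
                }
            )
    out = pd.DataFrame(rows)
    if not out.empty:
        out["residual_group_size"] = residual_group_size(out)
    return out
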