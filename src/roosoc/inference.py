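"""Permutation-based GLMM inference for network-metric effects.

Relational covariates (strength, clustering coefficient) violate the
independence assumptions behind Wald tests, so their significance is assessed
against data-stream permutations: swaps of individuals between groups in the
observation-level data, constrained to occur within survey sessions, keeping
the number and sizes of groups and every individual's sighting count exactly
fixed. The chain is sequential (a Markov chain started at the observed data):
each step applies a fixed number of accepted swaps (default 100), the first
burn-in steps are discarded (default 200), and after each of the kept steps
(default 1000) the association matrices, network metrics and residual group
size are recomputed, the model-ready records rebuilt, and the binomial
random-intercept GLMM refitted. The permutation p-value for a network term
compares the observed coefficient with the kept permuted coefficients using
the add-one rule; the default tail is two-sided (twice the smaller directional
tail, capped at 1) because selecting the tail by the observed sign doubles the
type-I error; tail="directional" gives the single tail in the observed
direction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .glmm import BinomialRandomInterceptGLMM, GLMMResult
from .metrics import fit_random_intercept_lm

logger = logging.getLogger(__name__)

NETWORK_TERMS = ("strength", "clustering")


@dataclass(frozen=True)
class ModelSpec:
    """One reproductive-success model: response, design, reference levels."""

    response: str                   # 'lpy' | 'pep' | 'wean'
    design: str = "approach1"       # 'approach1' | 'approach2'

    def __post_init__(self) -> None:
        if self.response not in ("lpy", "pep", "wean"):
            raise ValueError(f"unknown response {self.response!r}")
        if self.design not in ("approach1", "approach2"):
            raise ValueError(f"unknown design {self.design!r}")


@dataclass
class PermutationConfig:
    swaps_per_step: int = 100
    burn_in_steps: int = 200
    kept_steps: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.swaps_per_step, self.burn_in_steps, self.kept_steps) < 0 or self.swaps_per_step == 0 or self.kept_steps == 0:
            raise ValueError("permutation settings must be positive")


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)


class DesignInfo:
    """Model matrix for one design, with fast swap-in of network columns.

    Continuous sociability covariates measured on arbitrary scales (strength,
    residual group size) are z-standardized; clustering (already on [0, 1]),
    sighting counts and preferred-associate counts enter raw. Factor columns:
    year (reference = earliest) or 2-year period (reference = first label),
    parity (indicator for primiparous; reference = multiparous).
    """

    def __init__(self, records: pd.DataFrame, design: str):
        self.records = records.reset_index(drop=True)
        r = self.records
        n = len(r)
        cols: list[tuple[str, np.ndarray]] = [("intercept", np.ones(n))]
        cols.append(("strength", _zscore(r["strength"].to_numpy(float))))
        cols.append(("clustering", r["clustering"].to_numpy(float)))
        if design == "approach2":
            if "n_preferred" not in r:
                raise ValueError("approach2 records need an n_preferred column")
            cols.append(("n_preferred", r["n_preferred"].to_numpy(float)))
            fac, name = r["period"].astype(str), "period"
        else:
            fac, name = r["year"].astype(str), "year"
        levels = sorted(fac.unique())
        for lev in levels[1:]:
            cols.append((f"{name}-{lev}", (fac == lev).to_numpy(float)))
        cols.append(("parity-primiparous",
                     (r["parity"] == "primiparous").to_numpy(float)))
        cols.append(("residual_group_size",
                     _zscore(r["residual_group_size"].to_numpy(float))))
        cols.append(("n_sightings", r["n_sightings"].to_numpy(float)))
        self.terms = [c[0] for c in cols]
        self.X = np.column_stack([c[1] for c in cols])
        self.groups = r["female_id"].to_numpy()
        self._dyn = {t: self.terms.index(t)
                     for t in ("strength", "clustering", "residual_group_size")}

    def response(self, spec: ModelSpec) -> np.ndarray:
        return self.records[f"y_{spec.response}"].to_numpy(float)

    def with_network_columns(self, strength, clustering, resid) -> np.ndarray:
        X = self.X.copy()
        X[:, self._dyn["strength"]] = _zscore(np.asarray(strength, float))
        X[:, self._dyn["clustering"]] = np.asarray(clustering, float)
        X[:, self._dyn["residual_group_size"]] = _zscore(np.asarray(resid, float))
        return X


def fit_glmm(records: pd.DataFrame, spec: ModelSpec,
             re_var: float | None = None) -> GLMMResult:
    """Fit one reproductive-success GLMM (Laplace ML, female random intercept)."""
    info = DesignInfo(records, spec.design)
    res = BinomialRandomInterceptGLMM().fit(
        info.X, info.response(spec), info.groups, terms=info.terms, re_var=re_var
    )
    if not res.converged:
        logger.warning("GLMM %s/%s did not fully converge", spec.design, spec.response)
    if res.separation:
        logger.warning("GLMM %s/%s: possible separation", spec.design, spec.response)
    return res


def vif(records: pd.DataFrame, design: str = "approach1") -> dict[str, float]:
    """Variance inflation factors from the raw model matrix.

    VIF_k = 1 / (1 - R^2_k) from regressing predictor k on all other
    predictors (plus intercept); factor dummy columns are treated
    individually. Perfect collinearity reports as infinity.
    """
    info = DesignInfo(records, design)
    X = info.X
    out = {}
    for k, term in enumerate(info.terms):
        if term == "intercept":
            continue
        others = np.delete(X, k, axis=1)
        yk = X[:, k]
        beta, *_ = np.linalg.lstsq(others, yk, rcond=None)
        resid = yk - others @ beta
        tss = float(((yk - yk.mean()) ** 2).sum())
        rss = float((resid ** 2).sum())
        if tss == 0 or rss / max(tss, 1e-300) < 1e-12:
            out[term] = np.inf
        else:
            out[term] = 1.0 / (rss / tss)
    return out


class PermutationState:
    """Current permuted session -> group -> members assignment.

    Internally the assignment is one flat slot array: every (session, group)
    slot holds a female index, and a swap exchanges the contents of two slots
    of different groups in one session. The per-session group-size multiset,
    per-session attendee set and per-individual sighting counts are therefore
    invariant by construction; per-year co-group count matrices are either
    updated incrementally (:meth:`swap`) or rebuilt from the slot array by a
    sparse cross product (:meth:`rebuild_x`, used with :meth:`swap_batch` for
    large swaps-per-step settings).
    """

    def __init__(self, grouped: pd.DataFrame):
        from scipy import sparse  # noqa: F401  (used in rebuild_x)

        obs = grouped.drop_duplicates(subset=["session_id", "female_id"])
        self.ids = sorted(obs["female_id"].unique().tolist())
        self.index = {f: i for i, f in enumerate(self.ids)}
        years = (
            pd.to_datetime(obs["date"]).dt.year
            if "date" in obs else pd.Series(0, index=obs.index)
        )
        member: list[int] = []
        self._sess_meta: list[dict] = []
        year_slots: dict[int, list[int]] = {}
        year_gcode: dict[int, list[int]] = {}
        self._year_ngroups: dict[int, int] = {}
        for (sid, year), sess in obs.groupby([obs["session_id"], years], sort=True):
            year = int(year)
            year_slots.setdefault(year, [])
            year_gcode.setdefault(year, [])
            self._year_ngroups.setdefault(year, 0)
            ranges = []
            for _, members in sess.groupby("group_id"):
                s0 = len(member)
                gcode = self._year_ngroups[year]
                for f in members["female_id"]:
                    member.append(self.index[f])
                    year_slots[year].append(len(member) - 1)
                    year_gcode[year].append(gcode)
                ranges.append((s0, len(member)))
                self._year_ngroups[year] += 1
            self._sess_meta.append({"sid": sid, "year": year, "ranges": ranges})
        self._member = np.array(member, dtype=np.int64)
        self._year_slots = {y: np.array(v, dtype=np.int64) for y, v in year_slots.items()}
        self._year_gcode = {y: np.array(v, dtype=np.int64) for y, v in year_gcode.items()}
        # group sizes per slot are invariant under swaps
        self._slot_size = np.zeros(len(member), dtype=np.int64)
        for m in self._sess_meta:
            for s0, s1 in m["ranges"]:
                self._slot_size[s0:s1] = s1 - s0
        n = len(self.ids)
        self.n_sightings = {
            y: np.bincount(self._member[sl], minlength=n).astype(np.int64)
            for y, sl in self._year_slots.items()
        }
        self.swappable = [k for k, m in enumerate(self._sess_meta)
                          if len(m["ranges"]) >= 2]
        if not self.swappable:
            logger.warning("no session has two or more groups: chain cannot move")
        self.x: dict[int, np.ndarray] = {}
        self._x_stale = True
        self.rebuild_x()

    @property
    def years(self) -> list[int]:
        return sorted(self.x)

    @property
    def sessions(self) -> list[dict]:
        """Session -> group member lists view (reconstructed from the slots)."""
        return [
            {"sid": m["sid"], "year": m["year"],
             "groups": [list(map(int, self._member[s0:s1]))
                        for s0, s1 in m["ranges"]]}
            for m in self._sess_meta
        ]

    def swap(self, rng: np.random.Generator) -> None:
        """One accepted swap: exchange two individuals between two groups of
        one session (uniform among sessions with >= 2 groups), keeping the
        per-year co-group counts current."""
        if not self.swappable:
            raise ValueError("no swappable session (need >= 2 groups in a session)")
        meta = self._sess_meta[self.swappable[rng.integers(len(self.swappable))]]
        ranges = meta["ranges"]
        gi_a, gi_b = rng.choice(len(ranges), size=2, replace=False)
        (a0, a1), (b0, b1) = ranges[gi_a], ranges[gi_b]
        sa = a0 + int(rng.integers(a1 - a0))
        sb = b0 + int(rng.integers(b1 - b0))
        mem = self._member
        i, j = int(mem[sa]), int(mem[sb])
        if not self._x_stale:
            x = self.x[meta["year"]]
            rest_a = mem[a0:a1][mem[a0:a1] != i]
            rest_b = mem[b0:b1][mem[b0:b1] != j]
            if len(rest_a):
                x[i, rest_a] -= 1; x[rest_a, i] -= 1
                x[j, rest_a] += 1; x[rest_a, j] += 1
            if len(rest_b):
                x[j, rest_b] -= 1; x[rest_b, j] -= 1
                x[i, rest_b] += 1; x[rest_b, i] += 1
        mem[sa], mem[sb] = j, i

    def swap_batch(self, rng: np.random.Generator, n_swaps: int) -> None:
        """Apply ``n_swaps`` accepted swaps without maintaining co-group
        counts (call :meth:`rebuild_x` before reading matrices).

        Same Markov kernel as :meth:`swap`; this path makes large
        swaps-per-step settings affordable, which is what lets the chain
        decorrelate within a few steps on datasets of 10^3-10^4 observations.
        """
        if not self.swappable:
            raise ValueError("no swappable session (need >= 2 groups in a session)")
        u = rng.random((n_swaps, 5))
        mem = self._member
        swappable = self.swappable
        metas = self._sess_meta
        for k in range(n_swaps):
            ranges = metas[swappable[int(u[k, 0] * len(swappable))]]["ranges"]
            g = len(ranges)
            gi_a = int(u[k, 1] * g)
            gi_b = int(u[k, 2] * (g - 1))
            if gi_b >= gi_a:
                gi_b += 1
            a0, a1 = ranges[gi_a]
            b0, b1 = ranges[gi_b]
            sa = a0 + int(u[k, 3] * (a1 - a0))
            sb = b0 + int(u[k, 4] * (b1 - b0))
            mem[sa], mem[sb] = mem[sb], mem[sa]
        self._x_stale = True

    def rebuild_x(self) -> None:
        """Recompute per-year co-group counts from the slot array."""
        from scipy import sparse

        n = len(self.ids)
        for y, slots in self._year_slots.items():
            m = self._member[slots]
            ones = np.ones(len(m), dtype=np.int32)
            A = sparse.csr_matrix(
                (ones, (self._year_gcode[y], m)),
                shape=(self._year_ngroups[y], n),
            )
            x = np.asarray((A.T @ A).todense(), dtype=np.int32)
            np.fill_diagonal(x, 0)
            self.x[y] = x
        self._x_stale = False

    def hwi(self, years, id_subset: list[str]) -> np.ndarray:
        """HWI matrix over ``id_subset`` for the union of ``years``."""
        if self._x_stale:
            self.rebuild_x()
        idx = np.array([self.index[f] for f in id_subset], dtype=int)
        x = sum(self.x[y][np.ix_(idx, idx)] for y in years)
        ns = sum(self.n_sightings[y][idx] for y in years)
        from .associations import hwi_from_counts
        return hwi_from_counts(np.asarray(x), np.asarray(ns))

    def median_group_sizes(self, years, id_subset: list[str]) -> np.ndarray:
        """Median encountered group size per female over ``years``.

        Group sizes are fixed per slot; only who occupies a slot changes under
        permutation, so each female's encountered-size multiset varies with
        the assignment (even-length medians use the midpoint).
        """
        slots = np.concatenate([self._year_slots[y] for y in years])
        mem = self._member[slots]
        sz = self._slot_size[slots]
        order = np.lexsort((sz, mem))
        mem_s, sz_s = mem[order], sz[order]
        bounds = np.searchsorted(mem_s, np.arange(len(self.ids) + 1))
        out = np.full(len(id_subset), np.nan)
        for k, fid in enumerate(id_subset):
            i = self.index[fid]
            b0, b1 = bounds[i], bounds[i + 1]
            if b1 > b0:
                arr = sz_s[b0:b1]           # sorted ascending
                mlen = b1 - b0
                out[k] = (arr[mlen // 2] if mlen % 2
                          else 0.5 * (arr[mlen // 2 - 1] + arr[mlen // 2]))
        return out

    def session_snapshot(self) -> list[tuple[str, tuple[int, ...], frozenset]]:
        """(sid, sorted group sizes, attendee set) per session — the invariants."""
        out = []
        for m in self._sess_meta:
            sizes = tuple(sorted(s1 - s0 for s0, s1 in m["ranges"]))
            lo, hi = m["ranges"][0][0], m["ranges"][-1][1]
            out.append((m["sid"], sizes, frozenset(map(int, self._member[lo:hi]))))
        return out


def swap_step(state: PermutationState, rng: np.random.Generator) -> PermutationState:
    """One accepted swap as a free function; mutates and returns the state."""
    state.swap(rng)
    return state


def tail_pvalue(observed: float, permuted: np.ndarray, tail: str = "two-sided") -> float:
    """Add-one permutation p-value.

    'greater'/'less': fixed single tails; 'directional': the single tail in
    the observed direction; 'two-sided' (default): twice the smaller
    directional tail, capped at 1.
    """
    permuted = np.asarray(permuted, float)
    k = len(permuted)
    p_hi = (1 + int((permuted >= observed).sum())) / (k + 1)
    p_lo = (1 + int((permuted <= observed).sum())) / (k + 1)
    if tail == "greater":
        return p_hi
    if tail == "less":
        return p_lo
    if tail == "directional":
        return p_hi if observed >= 0 else p_lo
    if tail == "two-sided":
        return min(1.0, 2.0 * min(p_hi, p_lo))
    raise ValueError(f"unknown tail {tail!r}")


@dataclass
class ModelResult:
    """One model's table: Wald inference plus permutation p for network terms."""

    spec: ModelSpec
    glmm: GLMMResult
    perm_pvalues: dict[str, float] = field(default_factory=dict)
    perm_effects: dict[str, np.ndarray] = field(default_factory=dict)
    vifs: dict[str, float] = field(default_factory=dict)
    tail: str = "two-sided"

    def table(self) -> pd.DataFrame:
        rows = []
        for k, term in enumerate(self.glmm.terms):
            network = term in self.perm_pvalues
            rows.append({
                "term": term,
                "estimate": float(self.glmm.beta[k]),
                "se": float(self.glmm.se[k]),
                # z is not reported for permutation-tested network metrics
                "z": np.nan if network else float(self.glmm.zvalues[k]),
                "p": self.perm_pvalues[term] if network else float(self.glmm.pvalues[k]),
                "p_source": "permutation" if network else "wald",
            })
        return pd.DataFrame(rows)


class PermutationEngine:
    """Recompute metrics -> records -> GLMM refits along a swap chain.

    Parameters
    ----------
    grouped
        Grouped observation table covering every session of the design's
        periods (with a date column; swaps stay within sessions, matrices are
        rebuilt per period from per-year co-group counts).
    metrics
        The observed metrics table (eligible female-periods) whose
        median_group_size and n_sightings columns stay fixed; strength,
        clustering and residual group size are recomputed per permutation.
    records
        Observed model-ready records (subset of metrics rows with known
        parity and outcomes attached).
    periods
        list of Period the metrics were computed over.
    """

    def __init__(self, grouped, metrics, records, periods, design,
                 period_ids: dict[str, list[str]]):
        self.state = PermutationState(grouped)
        self.metrics = metrics.reset_index(drop=True)
        self.periods = {p.label: p for p in periods}
        self.design = design
        self.period_ids = period_ids
        # metric row -> (period label, position within the period id list)
        self._rowmap = []
        for rec in self.metrics.itertuples(index=False):
            ids = period_ids[rec.period]
            self._rowmap.append((rec.period, ids.index(rec.female_id)))
        self.records = records.reset_index(drop=True)
        key = list(zip(self.metrics["female_id"], self.metrics["period"]))
        lookup = {k: i for i, k in enumerate(key)}
        self._rec_to_metric = np.array(
            [lookup[(r.female_id, r.period)] for r in self.records.itertuples(index=False)],
            dtype=int,
        )
        self._lmm_X0 = np.column_stack([
            np.ones(len(self.metrics)),
            np.zeros(len(self.metrics)),
        ])
        self._lmm_groups = self.metrics["female_id"].to_numpy()

    def current_covariates(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(strength, clustering, residual group size) for the records rows.

        All three derive from the current permuted assignment: strength and
        binary clustering from the per-period association matrices, median
        group size from the permuted group memberships (sizes are invariant,
        occupancy is not), and the residual as the conditional residual of the
        permuted medians on permuted strength — the same function of the data
        stream that produced the observed covariates, which is what makes the
        observed coefficient exchangeable with the permuted ones under the
        null.
        """
        from .metrics import local_clustering, strength as strength_of

        per_period: dict[str, tuple] = {}
        for label, period in self.periods.items():
            ids = self.period_ids[label]
            h = self.state.hwi(period.years, ids)
            med = self.state.median_group_sizes(period.years, ids)
            per_period[label] = (strength_of(h), local_clustering(h), med)
        s = np.array([per_period[p][0][k] for p, k in self._rowmap])
        c = np.array([per_period[p][1][k] for p, k in self._rowmap])
        m = np.array([per_period[p][2][k] for p, k in self._rowmap])
        X = self._lmm_X0.copy()
        X[:, 1] = s
        fit = fit_random_intercept_lm(X, m, self._lmm_groups)
        resid = fit.conditional_residuals(X, m, self._lmm_groups)
        idx = self._rec_to_metric
        return s[idx], c[idx], resid[idx]

    def run(
        self,
        specs: list[ModelSpec],
        pconfig: PermutationConfig,
        tail: str = "two-sided",
        max_failure_rate: float = 0.01,
    ) -> dict[str, ModelResult]:
        """Fit observed models and permutation p-values for all ``specs``."""
        rng = np.random.default_rng(pconfig.seed)
        info = DesignInfo(self.records, self.design)
        fitter = BinomialRandomInterceptGLMM(var_tol=1e-3)
        observed: dict[str, GLMMResult] = {}
        for spec in specs:
            observed[spec.response] = BinomialRandomInterceptGLMM().fit(
                info.X, info.response(spec), info.groups, terms=info.terms
            )
        collected = {s.response: {t: [] for t in NETWORK_TERMS} for s in specs}
        failures = attempted = 0
        total = pconfig.burn_in_steps + pconfig.kept_steps
        for step in range(total):
            self.state.swap_batch(rng, pconfig.swaps_per_step)
            if step < pconfig.burn_in_steps:
                continue
            self.state.rebuild_x()
            s, c, r = self.current_covariates()
            X = info.with_network_columns(s, c, r)
            for spec in specs:
                attempted += 1
                try:
                    res = fitter.fit(
                        X, info.response(spec), info.groups,
                        terms=info.terms, start=observed[spec.response],
                    )
                    if not res.converged:
                        failures += 1
                    for t in NETWORK_TERMS:
                        collected[spec.response][t].append(res.coef(t))
                except (ValueError, np.linalg.LinAlgError):
                    failures += 1
            if failures > max(10, max_failure_rate * attempted):
                raise RuntimeError(
                    f"permutation refits failing too often ({failures} of "
                    f"{attempted}); aborting"
                )
        out = {}
        vifs = vif(self.records, self.design)
        for spec in specs:
            eff = {t: np.asarray(v) for t, v in collected[spec.response].items()}
            pvals = {
                t: tail_pvalue(observed[spec.response].coef(t), eff[t], tail)
                for t in NETWORK_TERMS
            }
            out[spec.response] = ModelResult(
                spec, observed[spec.response], pvals, eff, vifs, tail
            )
        return out


def permutation_pvalues(
    grouped: pd.DataFrame,
    metrics: pd.DataFrame,
    records: pd.DataFrame,
    periods,
    design: str,
    period_ids: dict[str, list[str]],
    specs: list[ModelSpec] | None = None,
    pconfig: PermutationConfig | None = None,
    tail: str = "two-sided",
) -> dict[str, ModelResult]:
    """Convenience wrapper: build the engine and run the chain for all responses."""
    specs = specs or [ModelSpec(r, design) for r in ("lpy", "pep", "wean")]
    engine = PermutationEngine(grouped, metrics, records, periods, design, period_ids)
    return engine.run(specs, pconfig or PermutationConfig(), tail=tail)
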