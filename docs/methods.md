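# Methods

`roosoc` implements a complete analysis chain for testing whether female
sociability predicts reproductive success in a fission–fusion macropod
society, together with a synthetic-society generator that stands in for
undeposited field data. This note documents the models, the numerical
choices, and what the synthetic world does and does not establish.

## From surveys to associations

**Grouping.** A survey session is an instantaneous snapshot of individual
positions (metres, planar). Groups are the connected components of the
proximity graph linking pairs within the chain threshold (default 15 m,
closed: exactly 15.0 m links). Singletons are groups. When only a recorded
group identifier exists (no per-member coordinates), the recorded assignment
is used as-is; when both exist, per-member positions win.

**Association indices.** Under the gambit of the group, all members of a
group are associating. With one sampling period per survey session, the
half-weight index for dyad (a, b) is

    HWI_ab = x / (x + y_ab + (y_a + y_b)/2)  =  2x / (n_a + n_b)

with x the co-grouped sessions, y_ab both-seen-split sessions, y_a/y_b
one-seen sessions, and n_i total sightings. Never co-observed dyads get 0,
not missing (dense matrices). The gregariousness-corrected index

    HWIG_ab = HWI_ab · (Σ_ij HWI_ij) / (Σ_i HWI_ai · Σ_j HWI_bj)

is invariant under uniform rescaling of all HWIs and removes individual-level
sociability from dyadic values. The correction is mean-field: it is exact
only in the limit where no single dyad dominates an individual's total
association; for an isolated dyad (n = 2) it is uninformative (identically
2 whenever any association exists). This matters for preferred-associate
detection below.

**Eligibility.** Single-year design: at least 10 survey sightings in the
year and reproductive-state records at least every 2 calendar months. We
additionally require the records to reach both year edges (first by
February, last by November); without the edge requirement a female seen only
in January–February would pass while her cohort's milestones fall in
entirely unobserved months. Two-year-window design: at least 10 sightings
and at least 50 GPS fixes within the window (the floor below which kernel
home-range estimates are unstable).

## Individual covariates

Strength is the HWI row sum; the local clustering coefficient is binary
(HWI > 0 edges), with degree < 2 mapped to 0 (flagged) so model rows
survive. Median encountered group size (females only; even-length medians
use the midpoint) is strongly collinear with strength, so the gregariousness
covariate is the conditional residual of

    median_group_size ~ strength + (1 | female)

fitted by profiled REML on group-level sufficient statistics (a hand-rolled
one-variance-component LMM, cross-checked against statsmodels MixedLM and
lme4; it exists because permutation inference re-fits it tens of thousands
of times). Degenerate designs (constant strength, one record per female)
fall back to a pseudoinverse fixed-effects fit, logged.

In the reproductive models, strength and residual group size are
z-standardized (effect scale: per SD); clustering (already on [0, 1]),
sighting counts and preferred-associate counts enter raw, matching the scale
of the reported per-sighting and per-associate coefficients.

## Preferred associates against a space-use null

Each female's utilization distribution is a Gaussian kernel density of her
GPS fixes (reference/Silverman bandwidth, 5 m cells, per-female grids),
normalized to 1. The null model replays every observed session with its
observed attendee set — holding observation effort, sighting frequencies,
session count and group-size-generating process fixed — while drawing each
attendee's position independently from her UD and re-assigning groups by the
chain rule. Each of 200 replicates yields a full HWIG matrix; a dyad is a
preferred associate iff its observed HWIG is strictly greater than the
ceil(0.975·200)-th order statistic (the 195th) of its null values. Per-female
preferred-associate counts feed the window design as a sociability covariate.

Calibration: for dyads whose null distribution has resolution, the rule's
false-positive rate is 5/201 ≈ 2.5% by exchangeability. Dyads with no
spatial overlap produce tie-heavy null distributions at zero and can only be
flagged less often — the rule is conservative there, never anti-conservative.
Sensitivity is a dyad-specific notion: a female who prefers many partners
raises her own gregariousness, and the HWIG correction deliberately
discounts all her dyads; detection is sharpest for preference concentrated
on single partners.

## Reproductive outcomes

Monthly state records (NPY, SPY, MPY, LPY, YAF, SPY+YAF, plus a suckling
flag) are parsed into young "episodes". A new pouch episode opens on a pouch
record or on stage regression (a smaller young implies a new birth).
Young-at-foot evidence belongs to the open nursing episode while plausible
(≤ 10 months past pouch exit: weaning is ~8 months post-exit and loss
follows soon after a failed weaning); later evidence marks a pouch exit and
attaches to the most recent episode that displayed LPY within the previous
four months — pouch exit follows the LPY stage, so an episode never seen at
LPY cannot claim it. Same-day conflicts resolve to the more advanced stage.

Outcomes per cohort: LPY iff the stage was displayed (or implied by a pouch
exit); PEP iff young-at-foot evidence exists; weaned iff no suckling is
recorded after the 8-month post-exit deadline. All three outcomes anchor to
the calendar year the young reaches LPY, which keeps wean ⇒ PEP ⇒ LPY true
within every row even when later stages straddle a year boundary. Extended
suckling past the deadline marks the cohort as not weaned; the rule is not
re-applied to grant a later weaning. Parity is multiparous with any inferred
earlier birth (birth years back-inferred from first-observed stages),
primiparous when the year holds her first recorded breeding and her history
starts early enough to have caught an earlier one, otherwise unknown
(excluded from models). Final-study-year pouch exits and weaning deadlines
are right-censored exactly as in any fixed-length field study.

## The GLMM and permutation inference

The reproductive models are binomial (logit) GLMMs with a female random
intercept, fitted by Laplace-approximated ML: a penalized Newton solve for
the joint (β, u) mode (Schur complement; the u-block is diagonal) inside a
1-D profile over log σ, with the criterion

    ℓ(σ) = max_{β,u} [loglik − Σ u²/(2σ²)] − ½ Σ_g log(1 + σ² W_g).

At σ² → 0 this is exactly ordinary logistic regression. The fixed effects
are profiled at the penalized mode (the `glmer nAGQ=0` construction, matched
to lme4 to ~1e-5 in tests; `nAGQ=1` differs by well under an SE). Wald SEs
come from the inverse Schur complement. Convergence uses a practical score
tolerance (1e-3) so quasi-separated nuisance terms (reported via a
separation flag) do not mask an otherwise-found mode.

Network-metric p-values come from constrained data-stream permutations:
swaps of two individuals between two groups of one survey session, which
exactly preserve group-size multisets, session attendee sets and individual
sighting counts. The chain runs forward from the observed data; after
burn-in, each kept step recomputes — from the permuted assignment — the
per-period HWI matrices, strength, clustering, median group size and its
residual on strength, rebuilds the model matrix and refits the GLMM.
Recomputing the medians per permutation is essential: the swap chain's
stationary law is uniform over assignments preserving the invariants, and
the observed data are one such draw under the exchangeability null, but only
if every covariate entering the model is the *same function* of the
assignment on both sides. Freezing the medians at their observed values
while permuting strength breaks that symmetry and measurably distorts the
test in both directions.

Two protocol levers matter in practice:

- **Mixing.** The p-value is the observed coefficient's rank among kept
  coefficients; it is only as good as the number of effectively independent
  permuted networks. One hundred swaps move ~1–2% of a field-sized stream,
  so short chains at that setting are badly under-mixed (we measured
  U-shaped p distributions and 5× inflated rejection). Swaps-per-step should
  be on the order of the observation stream's size when only a few hundred
  steps are kept; the batched swap path makes that affordable.
- **Tail.** The default p is two-sided (twice the smaller directional tail,
  add-one corrected, capped at 1). A single tail selected by the observed
  sign doubles the type-I error; the directional variant remains available
  as `tail="directional"`.

VIFs are computed from the raw model matrix, dummy columns individually;
perfect collinearity reports as infinity.

## The synthetic society

The generator states a world, once: ~120 females (IDs, isotropic
bivariate-normal range centres on a ~37 ha arena, daily-range dispersion
40 m), gamma-heterogeneous sighting propensities calibrated to the reported
median of ~64 sightings/female/year (range ~10–140) at 12 surveys/month,
preferred dyads sampled without replacement (default 150) whose members
relocate within 15 m of each other with probability 0.5 when co-present
(chains extend rather than break when dyads share members), and monthly
reproductive cycles: January/February births; SPY/MPY/LPY at months 0–3,
4–7, 8–10; pouch exit at month 11 (~46 weeks); weaning 8 months later.
Stage hazards are monthly loss rates realized at stage transitions, so every
reached stage displays its full duration and is observable under bimonthly
sampling. Conditional on pouch exit, weaning succeeds with probability
logit⁻¹ of a linear predictor in parity, year, and the female's realized
(not estimated) sociability covariates; default effect sizes are the
reported model magnitudes (strength −0.88/SD, parity −3.758, −0.093 per
preferred associate, year offsets 0/1.045/2.459/1.164). A failed weaner
keeps nursing three months past the deadline — the exact field signature the
weaning rule keys on — and the window is kept short enough that old-young
nursing and next-young emergence remain distinguishable.

What the generator does not emulate: habitat-driven aggregation (groups are
smaller than field reality because co-grouping arises only from range
overlap and pairwise preference), males, weather covariates, double
dependency beyond state labels, movement within sessions, and multi-year
range shifts. A green test therefore establishes the statistical machinery
on a structurally faithful but spatially stylized society, not ecological
realism.

Acceptance-grade properties are checked in purpose-built worlds: type-I
error in an exchangeable society (no preference, one shared foraging
ground — the null under which a permutation test's size is defined); effect
recovery in a world whose baseline weaning odds are even and whose pouch
hazards are zero, so the criterion's stated weaning-leg effect is the
model's estimand; spatial-null sensitivity with disjoint injected dyads,
the dyad-specific preference the gregariousness-corrected null isolates.

## Reproducibility

All randomness flows from explicit integer seeds through named substreams
(population, sessions, fixes, reproduction, null replicates, permutation
chain). Identical configuration and seed give byte-identical outputs; the
run manifest records the seed, thresholds, package version and per-period
filter counts.
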