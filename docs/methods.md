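# Methods

## The estimation problem

A durability cohort follows individually tagged LLINs from a mass
distribution campaign through survey rounds at 6, 12, 24 and 36 months.
At each round a net is recorded *present*, *not found* (given away,
stolen, exchanged, or the household could not say), or *discarded*
(destroyed by wear and tear, or repurposed). Three complications shape
the analysis:

1. **Interval censoring with ambiguity.** A net reported "not found" at
   one round and "discarded" at a later round may already have been
   destroyed at the earlier round, or still present then; the data cannot
   say. Deterministic cleaning would have to guess.
2. **Household clustering.** Nets in one household share exposure,
   behaviour and survey fate, so net outcomes are not independent.
3. **Shrinking denominators.** Unvisited households are not replaced, so
   the surveyed count falls sharply by 36 months and late-round
   proportions are noisy.

## Hole index and serviceability

Physical damage is summarised by the WHO proportionate hole index over
hole counts in four diameter classes (0.5–2, 2–10, 10–25, > 25 cm):

    pHI = n1 + 23·n2 + 196·n3 + 576·n4

with Good (pHI ≤ 64), Damaged (65 ≤ pHI ≤ 642), Torn (pHI > 642), and
"serviceable" meaning not Torn. The weights and thresholds are
deliberately hard-coded: they define the metric, and making them
configurable invites silent divergence from the scheme. Holes measured
exactly on a class boundary (2, 10 or 25 cm) are not resolved here —
field protocols assign them to a class before counting, and both the
synthetic generator and the file formats carry per-class counts only.

## Cleaning rules and their order

The cohort matrix is made monotone by three rules applied in a fixed
order: backfill presence, forward-fill discard, then mark ambiguous
cells UNKNOWN. The order matters: backfilling first resolves "not found
then seen again" sequences into presence, so that only genuinely
unresolvable not-found-before-discard cells remain for the UNKNOWN
pass; this order's fixpoint satisfies all three rule statements
simultaneously, and the composite pipeline is idempotent (a property
test checks this over random trajectories). Raw data in which a net is
present *after* a discard record contradicts the absorbing state and
raises an error naming the nets — silent repair would hide data-entry
faults.

Rounds where the household was not visited are UNSURVEYED and excluded
from every survey denominator. An alternative would be to lump them
with "not found"; we keep them distinct so that survey logistics never
inflate attrition estimates.

## Rate definitions

Both rates are proportions over nets surveyed at a round, with
two-sided 95% Wilson score intervals (chosen because late-round
denominators are small, where Wald intervals misbehave; computed via
statsmodels).

- *Survival rate*: present-and-serviceable nets over surveyed nets,
  excluding the not-found family (given away / stolen / exchanged, and
  absent nets with no recorded cause) from the denominator — those
  nets' ultimate fate is unknown, so they carry no information about
  physical decay.
- *Retention rate*: present nets over surveyed nets, excluding the
  discard family (damaged-and-discarded / repurposed).

Absent nets with no recorded cause appear in the cause table as
`unattributed` and take no part in the five-cause percentages, which
therefore sum to 100% of attributed losses.

The median survival time interpolates linearly between two time points
(by default the 12- and 24-month rates, in years):

    Tm = t1 + (t2 − t1)(p1 − 50) / (p1 − p2)

Its confidence interval applies the same formula to the lower limits of
p1 and p2 and to the upper limits, respectively. Two flags accompany
the estimate: a projection warning when p1 > 85% (interpolating toward
the median from so high a first point is unreliable), and an
extrapolation flag when the crossing falls outside [t1, t2] — the
formula supports extrapolation and well-retained products routinely
produce Tm beyond the last survey round, but such values should be read
as trend projections, not observations.

## The Bayesian survival model

Conditional presence per interval k (0→6, 6→12, 12→24, 24→36 months)
follows a logistic model:

    logit Pr(present at k | present at k−1) = α_bk (+ β·rural) + u_h
    u_h ~ Normal(0, σ²)

- The four intervals have unequal lengths and each gets its own
  parameter; no hazard rescaling is attempted, matching per-round
  reporting conventions.
- *Failure* is absence for any reason: a net given away has left the
  household just as a discarded one has. Unvisited rounds censor;
  a switch (`censor_not_found`) instead censors not-found nets for
  analysts who prefer to count only confirmed destruction as failure.
- Two variants: `per_brand` (independent α per brand, no covariate) and
  `zone_covariate` (brands pooled, rural indicator with coefficient β;
  exp(β) is the rural-vs-urban odds ratio of interval survival).
- Priors: Normal(0, 2.5²) on α and β — weakly informative on the logit
  scale, where ±5 already spans survival 0.7%–99.3% — and half-Normal(1)
  on σ. A Beta prior on the probability scale is available for the
  special case σ = 0 with no covariate, where it makes the survival
  update conjugate.

### Gibbs sampler

Each iteration alternates:

1. **Imputation.** After cleaning, every net trajectory is monotone, so
   its latent part reduces to the failure interval j ∈ {lp+1, …, fa},
   where lp is the last round seen present and fa the first round with
   a determined absence. The full conditional is
   P(j) ∝ (∏_{k=lp+1}^{j−1} p_k)(1 − p_j), sampled in one vectorised
   pass for all uncertain nets. This covers both UNKNOWN cells and
   unvisited rounds that lie *inside* an interval whose endpoint is
   determined (ignoring the latter would misattribute the failure
   round). Presence after a discard has probability zero by
   construction, and no sampled trajectory can revive a net. Degenerate
   conditionals (all path weights zero, possible only with boundary
   probabilities of exactly 0/1) resolve to the earliest absent
   interval and are counted and reported.
2. **Interval survivals.** Random-walk Metropolis on each α_bk
   (conjugate Beta draws in the σ = 0, Beta-prior case). A brand-interval
   with no nets at risk falls back to its prior, with a logged warning.
3. **Zone coefficient** (zone variant): random-walk Metropolis using
   the rural at-risk cells.
4. **Household effects.** A vectorised Metropolis sweep proposes a new
   u_h for every household simultaneously and accepts per household —
   valid because households are conditionally independent given the
   parameters.
5. **Random-effect scale.** Metropolis on log σ under the half-Normal
   prior, followed by a joint scaling move (u, σ) → (c·u, c·σ): the
   u-prior term cancels against the proposal Jacobian, so the move is
   cheap, and it breaks the funnel-shaped coupling that otherwise makes
   σ mix an order of magnitude more slowly.

Step sizes adapt toward 44% acceptance (30% for the scaling move)
during burn-in only, keeping the retained chain Markovian. Defaults are
4 chains × 5 000 iterations with 2 500 burn-in; chains run from
independent substreams of one seed, so every fit is exactly
reproducible. Split-R̂ and effective sample size (via ArviZ) are
attached per parameter; R̂ > 1.01 is flagged, not fatal. The experiments
shipped with the package (tests and the acceptance script) use 2 chains
and 1 500–3 000 iterations — enough for the posterior means, interval
coverage and conjugate comparisons they check, as their own tolerances
reflect.

Reported interval survivals s_bk = expit(α_bk) and their cumulative
products are conditional on u = 0 (a typical household) and, in the
zone variant, on the urban stratum; population-averaged survival under
σ > 0 is slightly closer to ½ than the typical-household value, which
matters when comparing against raw cohort proportions.

## Synthetic cohort generator

The generator draws household sizes (shifted Poisson), zones, one brand
per household (campaign distribution assigns a product per household),
and household effects, then simulates presence interval-by-interval
under exactly the model above — so the manifest's parameters are the
estimands of the recovery tests. Its defaults emulate a ~2 222-net,
eight-brand, two-zone cohort: per-brand interval survivals whose
24-month cumulative spans 51–88%, a near-lossless first half-year,
per-round cause weights reproducing an early-loss-by-giving-away /
late-loss-by-damage-and-theft pattern, per-round household missingness
that shrinks the surveyed count from ~2 222 to ~120 by 36 months, a
rural log-odds advantage of 0.924, and household scale 0.5.

Attrition causes are drawn at the failure round from per-round weights;
given-away/stolen/exchanged nets are observed NOT_FOUND and
discarded/repurposed nets DISCARDED. Holes arrive as cumulative Poisson
counts per size class (monthly rates × brand wear multiplier × per-net
gamma frailty standing in for usage intensity), so counts never
decrease and a heavy tail of torn nets appears late.

Two reporting-noise mechanisms, both off-switchable, create the
ambiguous cells the sampler exists for: a present net is reported
NOT_FOUND with probability 0.03 (not located during the visit), and a
freshly discarded net is first reported NOT_FOUND with probability 0.15
and confirmed DISCARDED at the next visit.

What the generator does **not** emulate: within-round event timing,
net-use covariates (washing, cooking-area exposure, sleeping-space
pressure), insecticide decay, spatial structure, and informative
missingness (households drop out independently of their nets' states).
Passing recovery tests therefore show that the estimator inverts its
own generative assumptions — clustering, competing causes, ambiguous
reporting, missingness — not that those assumptions hold in any
particular field dataset.

## Validation strategy

- Exact oracles: pHI arithmetic, threshold boundaries, cleaning-rule
  trajectories, the Tm formula, and cause-table percentages recomputed
  from published-scale count tables.
- Conjugate oracle: with complete data and no random effects, Gibbs
  posterior means equal the closed-form Beta mean
  (survivors + 1)/(at-risk + 2) within 3 Monte-Carlo standard errors.
- Parameter recovery: across 20 independent 1 000-net cohorts
  (σ = 0.5, β = 0.9), nominal 95% credible intervals for β and σ cover
  the truth in at least 17 of 20 fits.
- Invariants by property test: pHI additivity, cleaning idempotence,
  first-discard preservation, monotone coherence of every retained
  imputation, determinism under a fixed seed.

## Known limitations

- Single-site Metropolis updates mix adequately at these data sizes but
  would be slow for cohorts orders of magnitude larger; a Pólya-Gamma
  augmented sampler would be the natural upgrade.
- The rural/urban covariate enters the zone variant only; brand and
  zone are confounded in a campaign where brands are allocated by
  region, and the package does not attempt a joint brand × zone model.
- Cause-specific competing-risk survival (e.g. a give-away hazard vs a
  discard hazard) is summarised descriptively through the two rate
  definitions, not modelled jointly.
- Tm is an interpolation on two points, not a survival-curve estimate;
  its CI inherits whatever correlation p1 and p2 have, which the
  endpoint-pairing rule only approximates.
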