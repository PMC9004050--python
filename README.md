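# llinsurv

Survival, retention and attrition analysis for cohorts of long-lasting
insecticidal nets (LLINs).

National malaria programmes distribute LLINs in mass campaigns and need to
know how long the nets actually last in households: how fast they develop
holes, how many are given away, stolen or thrown out, and whether lifespan
differs by product brand or by rural/urban setting. The standard study
design follows a cohort of individually tagged nets over post-distribution
survey rounds (typically 6, 12, 24 and 36 months). `llinsurv` implements the
full analysis workflow for such cohorts, for field epidemiologists and
programme analysts:

- **Physical integrity** — the WHO proportionate hole index
  `pHI = n₁ + 23·n₂ + 196·n₃ + 576·n₄` over hole counts in four diameter
  classes, with the Good (pHI ≤ 64) / Damaged (65–642) / Torn (> 642)
  classification; a net is *serviceable* while pHI ≤ 642.
- **Cohort matrix cleaning** — observations are reorganised into a
  nets × rounds status lattice and made monotone: presence backfills earlier
  rounds, discard is absorbing and fills forward, and a "not found" report
  that precedes a later "discarded" report is marked UNKNOWN rather than
  guessed.
- **Rates** — per-round attrition-cause breakdowns; the *survival rate*
  (present **and** serviceable, with given-away/stolen/exchanged losses
  excluded from the denominator) and the *retention rate* (present, with
  discarded/repurposed losses excluded), both with 95% Wilson intervals;
  and the median survival time by linear interpolation,
  `Tm = t₁ + (t₂ − t₁)(p₁ − 50)/(p₁ − p₂)`, with a warning when the first
  time point exceeds 85%.
- **Bayesian survival model** — discrete-time survival on the logit scale,
  `logit Pr(present at k | present at k−1) = α_{bk} (+ β·rural) + u_h`,
  `u_h ~ N(0, σ²)`, fitted by Gibbs sampling with data augmentation: every
  UNKNOWN cell is re-imputed each iteration from its full conditional given
  the neighbouring known statuses, with zero probability of presence after a
  discard. One variant estimates independent interval survivals per brand;
  the other pools brands and estimates a rural/urban coefficient whose
  `exp(β)` is the odds ratio of survival.
- **Synthetic cohorts** — a generator with the same statistical structure
  (household clustering, competing attrition causes, progressive hole
  accumulation, per-round household missingness) plus a ground-truth
  manifest, used for calibration and parameter-recovery testing.

## Worked example

```python
import llinsurv as L

cfg = L.SimulationConfig(seed=7)                 # ~2222-net, 8-brand cohort
roster, obs, truth = L.simulate_cohort(cfg)
matrix = L.clean(L.build_matrix(roster, obs, rounds=cfg.rounds))
phi = L.phi_table(obs)

bd = L.reason_breakdown(matrix, 6)
print("absent at 6 months:", bd.total, "| given away:", bd.percentages["given_away"], "%")

sr = L.survival_rate(matrix, phi, 12)
print(f"12-month survival {sr.proportion:.1f}% (95% CI {sr.ci_low:.1f}-{sr.ci_high:.1f})")

spec = L.ModelSpec(variant="zone_covariate", chains=2, iterations=2000, burn_in=1000, seed=1)
eff = L.zone_effect(L.fit(matrix, roster, spec))
print(f"rural-vs-urban coefficient {eff['coefficient']:.3f}, OR {eff['odds_ratio_from_mean']:.2f}")
```

prints

```
absent at 6 months: 25 | given away: 52.0 %
12-month survival 93.6% (95% CI 92.2-94.8)
rural-vs-urban coefficient 0.810, OR 2.25
```

Of the 25 nets already absent at the first round, about half were given
away — early attrition in such cohorts is dominated by redistribution, not
damage. The 12-month survival rate counts nets still present and
serviceable among surveyed nets whose fate is known. The zone model, which
shares household random effects across a household's nets, recovers a
rural-vs-urban log-odds shift of 0.81 for this realisation (the generator's
true value is 0.924), i.e. rural households are roughly twice as likely to
keep a net alive through an interval.

The same stages are available from a shell:

```sh
llinsurv simulate --seed 7 --outdir data/
llinsurv clean --roster data/roster.csv --observations data/observations.csv --out matrix.csv
llinsurv rates --matrix matrix.csv --roster data/roster.csv --by brand --out rates.csv
llinsurv fit --matrix matrix.csv --roster data/roster.csv --variant zone_covariate --out posterior.csv
llinsurv report --seed 7 --outdir report/       # everything, in one bundle
```

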