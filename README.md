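# gallstone-cea

Cost-utility analysis of laparoscopic cholecystectomy (LC) versus
conservative management (CM) for adults with uncomplicated symptomatic
gallstones, built for health economists and methodologists who want a fully
testable, seeded reimplementation of a trial-based economic evaluation:

- a **synthetic trial generator** that emulates the statistical structure of
  a pragmatic two-arm randomized trial (217 participants per arm, 20 centres,
  24-month follow-up, cumulative surgical uptake 70.5% vs 29.5%, SF-6D-style
  utility trajectories with a transient post-operative decrement,
  missing-at-random questionnaire nonresponse) together with a closed-form
  oracle for the per-arm expected discounted costs and QALYs it implies;
- a **within-trial cost-utility analysis** at 24 months: QALYs by trapezoidal
  area under the utility curve with annual discounting (year one
  undiscounted, 3.5% thereafter), costs from a GBP 2019–2020 unit-cost
  table, adjusted incrementals Δ*C*, Δ*Q* (CM − LC) from regressions on arm +
  centre + age + sex + baseline utility, chained-equations multiple
  imputation pooled by Rubin's rules, joint non-parametric bootstrap, and
  ICER = Δ*C*/Δ*Q* with its cost-effectiveness-plane quadrant, CEAC
  Pr(λ·Δ*Q* − Δ*C* > 0), and incremental net monetary benefit;
- a **Markov cohort model** extrapolating to 10 years with monthly cycles:
  states NoSurgery → RecoveryTunnel (exact-dwell tunnel) →
  SymptomsResolved/SymptomsPersist, Death absorbing from every state via an
  age- and sex-specific life table; deterministic runs, probabilistic
  sensitivity analysis (beta/gamma parameter distributions), and an
  individual-level microsimulation oracle that must agree with the cohort
  totals.

See `docs/methods.md` for the model assumptions, default calibration, and
numerical conventions.

## Worked example

```python
import gallstone_cea as g

params = g.TrialParams(seed=3)                      # default study conditions
cohort = g.generate_cohort(params)                  # 434 participants
observed = g.apply_missingness(cohort, "MAR", params.missing_rate, seed=99)

result, draws = g.run_within_trial(observed, params, m=20, B=200, seed=5)
est = result.estimate
print(f"delta cost : {est.delta_cost:8.0f} GBP  95% CI {est.delta_cost_ci}")
print(f"delta QALY : {est.delta_qaly:8.4f}      95% CI {est.delta_qaly_ci}")
print(f"ICER       : {result.icer.icer:8.0f} GBP/QALY ({result.icer.quadrant})")
print(f"CEAC       : {result.ceac}")
```

prints

```
delta cost :    -1226 GBP  95% CI (-1530.093364359634, -900.690780568832)
delta QALY :  -0.0323      95% CI (-0.05267215094172732, 0.0010508859834927574)
ICER       :    38006 GBP/QALY (SW)
CEAC       : {13000.0: 0.995, 20000.0: 0.98, 30000.0: 0.785}
```

Conservative management saves about £1230 per participant while giving up
0.032 QALYs over two years. The quadrant label `SW` (cheaper, less
effective) matters: £38 006 per QALY here is the saving per QALY *forgone*,
so at the usual UK threshold of £20 000 per QALY the savings outweigh the
health loss, and the CEAC gives CM a 98% probability of being cost-effective
at that threshold.

The 10-year extrapolation runs the same comparison through the cohort model:

```python
lc, cm = g.MarkovSpec(strategy="LC"), g.MarkovSpec(strategy="CM")
det = g.compare_strategies(lc, cm)
psa_draws, psa = g.run_psa(lc, cm, g.PSAConfig.default(n_draws=1000, seed=7))
```

Everything is also reachable from the command line
(`gallstone-cea simulate | within-trial | model | psa | plot`); every output
file embeds the seed and a hash of the effective configuration.

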