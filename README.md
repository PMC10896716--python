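# easidemand

Food demand systems for household consumption surveys, and what they
imply for nutrition policy. The package estimates a censored EASI
(Exact Affine Stone Index) demand system for 18–19 food groups plus a
non-food numeraire from LSMS-style household panels, derives food and
nutrient elasticities, scores household diet quality, and simulates
cash transfers and food price discounts with programme-cost accounting.
It is aimed at applied economists and nutrition researchers who want a
tested, reproducible pipeline from item-level consumption records to
policy counterfactuals — and at method developers, via a synthetic-data
module that generates panels from known preferences so every stage can
be validated against ground truth.

## The model

Budget shares of food group *j* follow

&nbsp;&nbsp;*w<sub>j</sub>* = Σ<sub>r</sub> *b<sub>jr</sub>* *y*<sup>r</sup> + Σ<sub>k</sub> *a<sub>jk</sub>* ln *p<sub>k</sub>* + *y* Σ<sub>k</sub> *d<sub>jk</sub>* ln *p<sub>k</sub>* + **g**<sub>j</sub>′**z** + **m**<sub>j</sub>′**z̄**<sub>c</sub> + *e<sub>j</sub>*

with implicit utility (real expenditures)
*y* = (ln *x* − **w**·ln **p** + ½ ln **p**′A ln **p**) / (1 − ½ ln **p**′D ln **p**),
symmetry and homogeneity imposed on A and D, adding-up closing the
numeraire equation. Estimation is iterated linear 3SLS with three
corrections: the average-share Stone index instruments the endogenous
own-share deflator in *y*; leave-one-out neighbour prices instrument
quality- and search-contaminated unit-value indices (built as Fisher
Ideal indices within groups); and zero consumption (censoring) enters
through a probit-seeded, structurally refined participation correction
*w<sub>j</sub>* = Φ(*m<sub>j</sub>*/σ<sub>j</sub>)·*m<sub>j</sub>* + σ<sub>j</sub>φ(·).
Cluster-mean regressors (correlated random effects) absorb
time-invariant community preference heterogeneity. Expenditure and
Marshallian/Hicksian price elasticities are total derivatives of the
fixed-point demand and satisfy Engel/Cournot aggregation, homogeneity
and Slutsky symmetry to machine precision. See `docs/methods.md` for
the full account.

## Worked example

```python
import pandas as pd
pd.set_option("display.width", 120)
from easidemand import (SynthConfig, generate_preferences, generate_panel,
                        prepare, EASIDemandModel)
from easidemand import policy

cfg = SynthConfig(n_households=2000, n_waves=3, seed=1)
prefs = generate_preferences(cfg)           # ground-truth preferences
panel = generate_panel(cfg, prefs)          # item-level survey tables
data = prepare(panel)                       # shares, prices, instruments
res = EASIDemandModel(data, degree=2).fit()
print(res.summary())

es = res.elasticities()
print(es.median_by_quartile("expenditure").round(2).to_string())

ct = policy.CTConfig(transfer_monthly=policy.ct_transfer(data))
out = policy.simulate_cash_transfer(res, data, ct)
q1 = out.households[out.households.quartile == "Q1"]
print(f"CT: {ct.transfer_monthly:.2f} $/month; "
      f"Q1 DE sufficiency: {q1['suff_energy_kcal_pre'].mean():.1%} -> "
      f"{q1['suff_energy_kcal_post'].mean():.1%}")
```

Output (seed 1):

```
Censored EASI demand system
============================================================
observations: 6000   food groups: 6   degree R: 2   utility: exact
iterations: 90   converged dshare: 7.63e-09

own-price coefficients a_jj (se) and censoring rates:
  staple_grain       a_jj = +0.0383 (0.0223)   zero share: 14.1%
  starchy_staple     a_jj = -0.0409 (0.0298)   zero share: 4.1%
  pulses_nuts        a_jj = -0.0107 (0.0165)   zero share: 29.0%
  animal_source      a_jj = +0.0099 (0.0180)   zero share: 30.6%
  fruits_veg         a_jj = -0.0086 (0.0181)   zero share: 23.4%
  fats_oils          a_jj = -0.0041 (0.0234)   zero share: 10.4%
first-stage partial F (min over endogenous regressors): 1386.1
note: group animal_source: structural censoring scale out of band, keeping the probit correction
          staple_grain  starchy_staple  pulses_nuts  animal_source  fruits_veg  fats_oils  numeraire
quartile
Q1                0.55            0.71         1.03           1.01        1.25       0.81       1.43
Q2                0.38            0.60         1.08           1.06        1.11       0.80       1.34
Q3                0.11            0.47         1.10           1.08        1.03       0.78       1.29
Q4               -0.56            0.18         1.14           1.11        0.91       0.77       1.25
CT: 22.26 $/month; Q1 DE sufficiency: 10.8% -> 22.3%
```

The expenditure-elasticity table shows the textbook pattern the
generator encodes and the estimator recovers: staple demand is
expenditure-inelastic and falls away toward the top of the
distribution, while pulses, animal-source foods and (for the poor)
produce are expenditure-elastic. A cash transfer of 20% of the median
extreme-poor (Q1) household's monthly expenditures roughly doubles the
share of Q1 households meeting their dietary-energy requirement in
this synthetic population.

The full pipeline — simulate, prepare, fit, elasticities, diet quality,
CT and five price-discount scenarios, with a provenance manifest — runs
as

```bash
easidemand run --config cfg.yaml --out results/ --seed 1
```

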