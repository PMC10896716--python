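# Methods

## The demand model

Households allocate weekly total expenditures `x` across `J` food groups
and a composite non-food numeraire. Budget shares follow an EASI (Exact
Affine Stone Index) incomplete demand system: for food group `j`,

    w_j = Σ_r b_jr y^r + Σ_k a_jk ln p_k + y Σ_k d_jk ln p_k
          + g_j' z + m_j' z̄_c + e_j

where `y` is implicit utility (real total expenditures), `ln p` the
vector of log food-group price indices (the numeraire log price is
normalised to zero), `z` observable demand shifters (log household
size, urban residence, head age) plus wave dummies, and `z̄_c` cluster
means of prices, log expenditures and shifters — a Mundlak–Chamberlain
correlated-random-effects device absorbing time-invariant community
preference heterogeneity. The numeraire equation follows by adding-up.

Implicit utility is the exact affine Stone index

    y = (ln x − w·ln p + ½ ln p' A ln p) / (1 − ½ ln p' D ln p).

With `A` and `D` symmetric this choice makes the Slutsky matrix of the
fixed-point demand exactly symmetric at **any** price vector, so Engel
aggregation, Cournot aggregation, homogeneity and Hicksian symmetry all
hold to machine precision — the test suite asserts 1e-8. A
Stone-approximate flavour (`utility="stone"`, `y = ln x − w·ln p`) is
retained as an option; its identities are exact only at base prices.
Because `y` depends on `w` and vice versa, predictions solve the joint
fixed point by damped iteration (damping 0.5, tolerance 1e-10, start at
`y⁰ = ln x`); the derivative algebra used for elasticities implicitly
differentiates the same fixed point, giving

    ∂y/∂ln x = 1/(Δ + S),   ∂y/∂ln p_k = −w_k/(Δ + S),

with `Δ = 1 − ½ ln p'D ln p` and `S = Σ_k ln p_k ∂m_k/∂y`.

### Restrictions

Symmetry is imposed by sharing one free parameter per `{j,k}` pair of
`A` and `D`; homogeneity and adding-up define the numeraire row/column
of the full `(J+1)×(J+1)` matrices (rows sum to zero) and the numeraire
polynomial/shifter coefficients. Estimates therefore satisfy the
restrictions identically, and simulated parameter draws do too.

## Estimation

The `J` food-share equations (numeraire dropped) are estimated by
iterated linear instrumental variables on the stacked system with
cross-equation restrictions:

1. **Endogeneity of real expenditures.** The household's own Stone
   index contains its own shares, so `y` is instrumented by powers of
   the average-share-deflated log expenditure
   `y* = ln x − Σ_k w̄_k ln p_k` (sample-average shares `w̄`).
2. **Endogeneity of unit-value prices.** Quality choice within groups
   and price search make household price indices correlate with
   expenditures and the taste error. Within-group quality composition
   is absorbed by a Fisher Ideal index at the group level; the
   remaining household-specific component is instrumented by
   leave-one-out cluster-wave mean log prices (neighbour prices) and
   their interactions with `y*`.
3. **Censoring.** Zero consumption in the 7-day recall is handled by a
   two-step censored-system correction. A probit participation model
   per censored group (on the exogenous regressors and instruments)
   seeds the correction in Shonkwiler–Yen form
   `w_j = Φ_j·(latent index) + θ_j φ_j`. Because the probit index is
   only a projection of the true participation index `m_j/σ_j`, the
   fit then switches to *structural* participation fields: `Φ` and `φ`
   are rebuilt from the model's own latent prediction `m̂_j` with
   `σ_j` calibrated so the implied zero probability matches the
   group's observed zero rate, and the `σ_j φ_j` term moves to the
   left-hand side (a freely estimated loading is collinear with the
   `Φ`-scaled regressors). Three structural passes are run; at the true
   parameters the correction is exact. The calibrated `σ̂_j` must lie
   within a factor of four of the equation's residual scale — a root
   outside that band signals an untrustworthy latent mean, and that
   group reverts to the probit fields (noted in the fit report). The
   final `σ̂_j` is reported as the censoring loading `theta` and
   typically recovers the true latent error scale within a few percent
   on synthetic data.
4. **Weighting.** After convergence the system is re-solved with
   three-stage-least-squares weighting (inverse residual covariance
   across equations). This matters for small-share groups, whose
   elasticities divide by small `w_j`. If the residual covariance is
   near-singular (e.g. a noiseless fit), the unweighted solution is
   kept and noted.

Each pass iterates the linear IV solve with the implicit-utility update
`y ← y(A, D, w_obs)` until the maximum change in predicted shares falls
below 1e-8. Standard errors are heteroskedasticity-robust and clustered
at the household level; the parameter covariance covers the free
(restriction-reduced) vector, so multivariate-normal simulation draws
respect symmetry and homogeneity by construction. Polynomial degree is
selected by BIC on the system residuals (`select_degree`), with every
candidate's criterion recorded.

Prediction of observed (censoring-adjusted) shares uses the same
participation fields as estimation — this keeps predictions
mean-consistent with the fitted data — and renormalises the final
vector onto the simplex, logging the renormalisation magnitude.

### A note on price normalisation

Any group price index fixes an arbitrary per-group base constant.
Under the exact affine Stone index those constants enter the quadratic
terms of `y`, so the model class is not exactly closed under re-basing:
even a noiseless end-to-end run recovers the generating coefficients
only to ~1e-3. The estimator-isolation tests therefore feed the exact
generating prices (`synth.prepared_from_truth`); statistical recovery
through the full unit-value/Fisher pipeline is what the confounded
recovery check measures (median own-price elasticity error ≈ 0.08,
tolerance 0.1, at 2,000 households × 3 waves).

## Survey preparation

* **Unit values**: purchases keep own value/quantity; other records get
  the median purchaser unit value at the smallest geography (cluster →
  stratum → national) with at least `min_count` (default 5) purchase
  observations.
* **Fisher group indices** against wave-1 sample-mean item prices and
  quantities; a household's missing items enter through imputed unit
  values, and an empty current basket falls back to the Laspeyres leg.
* **Expenditure aggregate**: unit-value-valued food (all sources) plus
  non-food; adult equivalents use a configurable age scale (default:
  under-15 count 0.5, 60-plus 0.8); expenditure groups use the
  1.90/3.20/5.50 US$ PPP per-AE-per-day cutoffs, half-open and
  lower-inclusive.
* Weekly values convert to daily by /7 and to monthly by (365.25/12)/7.

## Elasticities

Expenditure and Marshallian/Hicksian price elasticities are total
derivatives of the latent fixed-point demand at each observation (the
`(J+1)`-good system including the numeraire). Cells with predicted
shares below 1e-4 are flagged unstable and excluded from quartile
medians. Simulation standard errors draw parameter vectors from
`N(β̂, Cov̂)` (default 1,000 draws, seed recorded) and accumulate
per-cell Welford moments; draws whose fixed point diverges are skipped,
and cells unstable in some draws accumulate over the finite ones.
Nutrient-intake elasticities weight food elasticities by the
observation's nutrient source shares `s_nj = q_j c_nj / Σ_m q_m c_nm`,
and the response to a staple price splits into own
(`s_nk ε_kk`) and cross (`Σ_{j≠k} s_nj ε_jk`) channels.

## Diet quality

* **Sufficiency**: 7-day intake of energy, carbohydrate, protein, fat,
  iron, zinc, vitamin A and folate against the household requirement —
  the sum over members of age-sex class EER/EAR values times seven,
  boundary-inclusive. The shipped 14-class requirement table is a
  documented synthetic stand-in with plausible magnitudes, replaceable
  via `requirements=`.
* **Macronutrient balance**: shares of macronutrient-derived energy
  (Atwater 4/9/4) against the WHO ranges 10–15% protein, 15–30% fat,
  55–75% carbohydrate, boundary-inclusive, so the three shares sum to
  one by construction.
* **NRFI**: an NRF9.3-style score on a 2,000 kcal basis — nine
  qualifying densities (protein 50 g, fibre 28 g, vitamin A 900 µg,
  vitamin C 90 mg, vitamin E 15 mg, calcium 1,300 mg, iron 18 mg,
  magnesium 420 mg, potassium 4,700 mg) each capped at 100% of the
  reference, minus uncapped moderation densities (saturated fat 20 g,
  added sugar 50 g, sodium 2,300 mg). The score is invariant to
  uniform scaling of the whole diet, which removes common quantity
  misreporting.

## Policy simulations

The cash transfer adds 20% of the median Q1 household's monthly
expenditures (flat per household; spend fraction κ, default 1, is the
portion assumed to raise total expenditures) on the weekly accounting
basis; demand re-solves at unchanged prices. Price discounts multiply
the targeted category's prices by (1−δ), δ = 0.25, covering all
consumption regardless of source (imputed unit values measure
opportunity cost; a purchases-only switch exists). Demand re-solves at
unchanged expenditures, and the programme cost is the redeemed value
`δ p⁰ q_post`, reported monthly by quartile. Counterfactuals shift
prices, expenditures and their derived instruments but hold the
cluster-mean regressors and quartile labels at baseline: the former
proxy time-invariant preferences, the latter define the
pre-intervention targeting groups. Producer prices and wages are fixed
by assumption. Sufficiency-versus-expenditure curves use a Gaussian
local-averaging smoother on log per-AE expenditures with bandwidth
0.25 log points, trimmed where kernel mass is negligible.

## Synthetic data

The generator emulates LSMS-style panels: 2,000 households × 3 waves
(clusters of ~20 households, 5 clusters per stratum), 7-day recall for
six food groups × 3 items plus a numeraire, log-normal per-AE daily
expenditures (median ≈ 2.6 US$ PPP, σ = 0.8, putting roughly a third
of households under the 1.90 $ line), cluster×wave log price shocks
(σ = 0.2), item-level quality and price-search loadings of 0.1 on
standardised log expenditures and the standardised taste error
(making unit values genuinely endogenous), latent share errors scaled
to produce ~15% zero consumption (censored mass reassigned to the
numeraire), and a small cluster taste component correlated with
cluster prices (what the CRE terms absorb). Rosters draw sizes
1+Poisson(3) with child/adult/elder age mixture; the toy composition
table implements dietary archetypes (staple grain, starchy staple,
pulse, animal-source, fruit/vegetable, oils, …) with Atwater-consistent
energy.

Two stylised facts of the setting are built into the preference and
price draws. Base price levels are anchored to energy density through
archetype price-per-calorie rates (staples ≈ 0.4 US$/1,000 kcal,
animal-source ≈ 3.5, produce ≈ 3.0, oils ≈ 0.35; 15% jitter), so cheap
calories come from staples and dietary-energy affordability is stable
across seeds. Engel slopes carry their textbook signs — staple shares
decline and animal-source/produce/pulse shares rise with the living
standard — plus a common drift of about −10 pp of food share per log
point of real expenditures (Engel's law), giving Q1 food shares ≈ 0.6
against ≈ 0.45 for Q4. Baseline Q1 dietary-energy sufficiency lands
around 1–12% depending on the draw, rising steeply through Q2–Q4; the
shipped requirement table is on the demanding side (moderate-activity
adults), so absolute sufficiency levels are lower than in surveyed
populations while the expenditure gradient matches.

What the generator does **not** emulate: seasonality, attrition,
recall measurement error, food away from home, intra-household
allocation, or real food-composition matching. Passing tests therefore
demonstrate internal consistency of the estimator and simulator under
the stated assumptions, not performance on real surveys.

## Numerical choices and test scales

Fixed-point tolerance 1e-10 (prediction) / 1e-8 on share changes
(estimation), damping 0.5, deterministic initialisation; probit indices
clipped at ±8; share floor 1e-4 for elasticity division; simulated-SE
draws skipped on divergence. Test problem sizes are scaled to the
information each check needs: estimator-isolation and unit tests use
300–400 households × 2 waves; recovery and policy ground-truth checks
use the default 2,000 × 3 conditions (recovery over ten seeds); the
re-simulation oracle for mean observed shares uses 12 independent
seeds at 800 × 2. The policy ground-truth comparison runs with
quality/search/item-price noise at zero so that the model route and
the true-preference route condition on the same measured prices: with
confounding on, the two accounting bases differ per household by ~10%
in intake, which threshold functionals amplify into sufficiency-share
differences that reflect measurement, not simulation fidelity (the
confounded setting is exactly what the recovery check measures).

## Known limitations

* The censoring correction is a two-step unconditional-mean device,
  not maximum simulated likelihood for a multivariate Tobit; its
  standard errors ignore the generated-regressor step (simulation SEs
  for elasticities are available and recommended for reporting).
* Elasticities describe the latent (notional) demand; policy
  simulations use the censoring-adjusted mean re-solution, so threshold
  outcomes near zero consumption are handled there rather than through
  elasticity approximations.
* Price-index base constants interact with the exact-affine quadratic
  terms (see above); comparisons of raw coefficient values across
  different price normalisations are not meaningful, elasticities are.
* The shipped composition and requirement tables are synthetic
  stand-ins; all diet-quality conclusions on synthetic data are
  relative to them.
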