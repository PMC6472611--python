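# Methods

## Model overview

`ppadopt` couples three submodels, advanced on an annual time step (Euler,
dt = 1 year, matching annual cropping decisions) over a default horizon of 25
years for a population of `X = 1000` households already growing annual
pigeonpea:

1. a **production model** mapping a season-quality index to annual- and
   perennial-system yields;
2. a **preference model** summing attribute utilities into `U_a` and `U_p`
   and converting them into a logit choice probability `Pa`;
3. a **diffusion model** moving farmers between the non-adopter, adopter and
   disadopter stocks under the influence of skills/confidence, trust/distrust,
   seed supply, exogenous promotion, disappointment and social conformity.

The population is well mixed (no network topology); heterogeneity of costs and
benefits across farmers is represented implicitly by the logit, whose inputs
are population-mean utilities.

## Production

**Season quality.** A dimensionless index `s ∈ [0.2, 1.6]`, interpreted as a
season's sole-maize yield relative to the long-run average — a proxy for
rainfall-driven growing conditions. Stochastic runs draw `s` i.i.d. each year
from a beta distribution rescaled onto the support. The shape parameters are
not identified by the available information beyond the support and an average
season of 1; the defaults `alpha = 4, beta = 3` make the rescaled mean exactly
`0.2 + 1.4·(4/7) = 1.0` with a realistic left-skewed spread (sd ≈ 0.25). Both
shapes are configurable.

**Yield envelopes.** For each crop the mean yield line is `s` times the crop
average (defaults: maize 2800 kg/ha, pigeonpea 289 kg/ha, typical of a
low-potential central-Malawi site), with an uncertainty band of ±15% of the
mean line; stochastic yields are drawn uniformly inside the band,
deterministic runs use the midpoint. Linear-in-`s` bands are the
fewest-parameter form consistent with the causal chain rainfall → maize →
pigeonpea; the true crop-model envelopes are certainly curvier, but within
the support the difference is second-order relative to the behavioral
uncertainties. Woody stem biomass is proportional to pigeonpea grain
(default 3 kg biomass per kg grain, configurable) — a simple allometric
stand-in where measured ratios are unavailable.

**Ratoon effect.** The perennial system's yields are the annual system's
times a crop- and season-specific multiplier, interpolated piecewise-linearly
through anchors at a very dry (`s = 0.2`), normal (1.0) and very wet (1.6)
season and clamped outside the support (so extrapolation can never produce a
negative multiplier). Defaults — maize 0.80/0.95/1.10, pigeonpea
1.30/1.10/0.90 — encode the observed sign pattern: the established, deeper-
rooted ratooned shrub wins in dry years at some cost to the intercropped
maize, and loses ground in wet years. The perennial system runs a three-year
cycle (establishment year = annual yields; two ratooned years). The
population-level simulation uses the **cycle-average multiplier**
`(1 + 2m)/3` rather than tracking each household's phase: the model is
aggregate, households' cycles would be desynchronized in reality, and phase
tracking would add state without changing the population mean.

**Grazing.** The grazing scenario removes the perennial system's pigeonpea
grain and biomass (free-ranging dry-season livestock consume the standing
crop) and suppresses the soil-fertility attribute; maize, harvested before
the dry season, and the labor-savings attribute are unaffected.

## Preferences and calibration

Utilities are additive and linear in yields: per-kg marginal utilities for
maize grain, pigeonpea grain and biomass, plus fixed soil-fertility and
labor-savings attributes for the perennial system only. The choice
probability is the numerically stable logistic of `U_p − U_a`.

The original stated-preference coefficients are not available, so
`ppadopt.synthetic.calibrate_coefficients` builds a synthetic set pinned to
the one published anchor: at average yields in a normal season the utility
difference `U_p − U_a` equals **1.2**, which reproduces the 77% baseline
choice probability exactly. Remaining degrees of freedom are fixed by
documented choices:

* **Scale** (`base_utility = 3.0`): the absolute level of `U_a` at the
  anchor. The difference is scale-free but the *ratio* `U_p/U_a` — which
  drives the skill-transfer and willingness ramps and the disappointment
  trigger — is not. The scale is chosen so that ordinary season swings move
  the relative-performance ratio by more than the 10% disappointment
  threshold: at much larger scales the ratio is inert and the
  disappointment/trust dynamics that the model exists to study never
  activate.
* **Attribute shares** (maize 0.45, pigeonpea grain 0.03, biomass 0.52 of
  `U_a`): maize is valued ≈1.55× pigeonpea grain per kg (farmers weight
  maize more), while the pigeonpea-linked terms (grain + biomass) jointly
  outweigh the maize term. The latter is required for wetter-than-average
  seasons to *suppress* the perennial advantage under the ratoon-anchor
  defaults: maize gains in wet years would otherwise dominate. The implied
  high per-kg biomass utility reflects strong household demand for fuelwood
  relative to its small quantity.
* **Extras split** (soil 60% / labor 40%): the perennial-only surplus —
  the part of the 1.2 the yield terms do not provide — is split between the
  soil-fertility and labor-savings attributes. Nothing downstream depends on
  this split; it is exposed for sensitivity work.

Calibration is exact (|achieved − target| < 1e-9) and is anchored at fixed
reference yields (2800/289), so scenario sweeps over the production
environment change the environment, not the farmers' preferences. Negative
perennial-attribute utilities are permitted: the utility-shock scenario
(difference 1.2 → −1.0) and even a calibration target of 0 require them.

## Diffusion

**Adoption.** `R = N · (C/X) · T · Pa`, capped by the seed constraint and by
`N`. `C` is the cumulative count of skilled-and-confident farmers (permanent,
never decreasing), `T` the trusting proportion. Seed supply is affine in the
previous year's adopters, `S = 10 + 2·A_prev`: a base trickle plus two
farmers' worth of seed saved per current grower.

**Skills and risk aversion.** Adopters mentor at 0.1 trainees per adopter
per year at utility parity (ten adopters train one farmer), ramping linearly
to 2.0 at double-or-more relative utility; of those trained, the proportion
willing to try ramps from 40% at parity to 80% at double utility. The
reduced-risk-aversion scenario raises the ramp floor to 80%.

**Disappointment.** When the perennial is inferior (`U_p < U_a`) the direct
disadoption rate is one minus the three-year mean of `Pa` (averaged over the
available years before year 3). Otherwise, if this year's relative
performance is ≤ 90% of last year's, a ramp rises linearly from 0 at ratio
0.9 to 10%/yr at ratio 0. The indirect term `A·L/I` applies in all cases with
the same conformity divisor `I = 20` (the constant printed in the inferior
case is read as that same divisor, not a second parameter).

**Trust.** The trust/distrust stocks' transfer law is the model's least
constrained piece; the implemented law is:

* gain pressure `(A·10·Pa3 + N·10·0.01)/X` recruits from the *neutral*
  remainder `1 − T − L`;
* loss pressure `(D·20·min(1, 1 − Pa3))/X` transfers trust to distrust;
* both saturate as `1 − exp(−x)` so per-capita persuaded fractions stay in
  [0, 1];
* distrust **fades** toward neutral at 0.2/yr — peer pressure wears off when
  not renewed;
* readoption equals the disadopter stock times the population's trust gain,
  scaled by a **conformity resistance** `1 − 0.5·σ·(D/X)` (floored at 0),
  where σ is the product of the three social factors relative to defaults
  (σ = 1 at defaults, 8 in the conformity scenario).

The last two elements are deliberate design: without fade, distrust ratchets
irreversibly and the post-shock system can never stabilise; without the
conformity resistance, adopter persuasion saturates and neither the
recovery/no-recovery contrast after the utility shock nor the multiplicative
tipping point of the three social factors can arise — the doubled factors all
saturate individually at realistic stock sizes. The resistance term encodes
conformity as pressure toward the majority: a large disadopting crowd makes
returning socially costly.

**Promotion.** While adoption ≤ 10%, an outside program equips 10 farmers/yr
with skills and trust; they bypass the seed constraint (externally supplied)
and adopt at probability `Pa`. This seeding is essential: with
`promotion_rate = 0` the system never ignites (covered by a test).

**Order within a year**: production → utilities/`Pa` → promotion →
confidence → trust → adoption → disadoption → readoption. All flows are
clamped to their source stocks; conservation `N + A + D = X` holds to
1e-9·X after every step.

## Scenario engine and reproducibility

A `ScenarioConfig` fully determines a run. Ensembles draw per-iteration
streams from `SeedSequence((master_seed, iteration))`, so results are
reproducible bit-for-bit and independent of iteration order. Ensemble
summaries report the per-year mean/min/max of the adopter share. The
conformity scenario's "average adoption level" is operationalised as the
ensemble-mean adopter share in the final year. Named fixtures (`baseline`,
`stochastic`, `grazing`, `shock`, `conformity`, …) pin the canonical
experiments.

Default problem sizes: 25 years × 1000 households per run; ensembles of 1000
iterations by default, with 200 iterations used in the shipped acceptance
checks and tests (the ensemble mean of the final-year share moves by well
under one percentage point between 200-iteration seeds).

## What the synthetic data does and does not show

The season generator emulates the *distribution* of season quality (support,
mean, skew) but not multi-year autocorrelation, trends, or the specific
1980–2006 sequence; seasons are i.i.d. The calibrated coefficients reproduce
the baseline utility gap exactly but the split across attributes is an
identified-only-in-total construction. Consequently, passing tests establish
the internal mechanics (conservation, ramps, tipping behavior, orderings) and
reproduction of the anchored quantities; they do not validate attribute-level
preference magnitudes or season persistence effects against real data — no
empirical adoption data for this technology exists.

## Numerical choices

* Logit computed via the stable one-sided `exp` formulation; valid to
  |difference| ≈ 700.
* `U_p/U_a` falls back to `1 + (U_p − U_a)` when `U_a ≤ 0` (the ratio is
  meaningless at non-positive base utility).
* Boundary conventions: promotion threshold inclusive ("10% or less");
  disappointment triggers at ratio ≤ 0.9; the three disadoption cases are
  exclusive with `U_p = U_a` routed to the non-inferior branch.
* Performance ratio defined as 1 in year one (no history).
* Piecewise-linear interpolations are clamped at their endpoints.
* Deterministic runs ignore the master seed entirely (no draws are made).

## Known limitations

* Doubling the pigeonpea-grain utility nudges the trajectory slightly
  *down* (the extra utility inflates both systems, diluting the relative
  ratio that drives the ramps) rather than slightly up; both effects are
  near-null, consistent with maize dominating farmers' valuations.
* The high-conformity + low-risk-aversion combination stabilises at low
  adoption rather than oscillating; the oscillatory regime presumably
  requires a different trust-transfer law.
* The deterministic baseline saturates by year 12, a faster approach than
  the gradual curve the calibration anchors describe; the year-12 share is
  treated as a lower bound.
* Aggregate cycle-average accounting ignores household-level ratoon-phase
  composition effects, and the well-mixed assumption ignores network
  structure entirely.
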