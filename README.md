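# ppadopt

Ex-ante simulation of the adoption of **perennial (ratooned) pigeonpea** in
Malawian maize–pigeonpea systems. Pigeonpea (*Cajanus cajan*) is a woody,
nitrogen-fixing legume normally replanted every year; cutting the stem near
the ground after harvest ("ratooning") lets the same plant regrow for two
more seasons, saving seed and labor and building soil fertility — but it asks
farmers to manage a familiar crop in an unfamiliar way, in a climate where
yields swing hard from year to year.

`ppadopt` is a stochastic stock-and-flow model of how such a technology
spreads through a population of 1000 pigeonpea-growing households over 25
years. It is aimed at researchers in agricultural innovation and system
dynamics who want to explore how climatic stochasticity interacts with trust,
skill transfer, risk aversion and social conformity to shape adoption
trajectories.

## The model

Three behavioral stocks — non-adopters `N`, adopters `A`, disadopters `D` —
exchange annual flows (`N + A + D = X` always):

* **Choice.** Each system's utility is the sum of attribute utilities:
  marginal utility per kg of maize grain, pigeonpea grain and woody biomass,
  plus soil-fertility and labor-savings attributes for the perennial system.
  The probability a farmer prefers the perennial system is the binary logit
  `Pa = e^{U_p} / (e^{U_p} + e^{U_a})`. At the calibrated baseline gap
  `U_p − U_a = 1.2` this gives `Pa = 0.77`.
* **Adoption.** `R = N · (C/X) · T · Pa`, capped by seed supply
  `S = 10 + 2·A` and gated by the cumulative count `C` of farmers with skills
  and confidence and the trusting proportion `T`. An outside program promotes
  10 confident, trusting farmers per year while adoption is at or below 10%.
* **Disadoption.** Direct disadoption from disappointing performance — one
  minus the three-year mean of `Pa` when the perennial is inferior, or a ramp
  rising to 10%/yr as this year's relative performance falls below 90% of
  last year's — plus indirect disadoption `A · L / I` from the distrusting
  proportion `L` under conformity pressure `I`.
* **Trust and readoption.** Adopters persuade 10 peers/yr (persuasiveness =
  three-year mean `Pa`), disadopters discourage 20 peers/yr (persuasiveness =
  one minus that), non-adopters chat at 1% persuasiveness; distrust fades as
  peer pressure wears off. Disadopters who regain trust re-adopt, resisted by
  conformity toward a large disadopting crowd.
* **Production.** A season-quality index on [0.2, 1.6] (beta-distributed,
  mean 1) scales linear yield envelopes around the averages 2800 kg/ha maize
  and 289 kg/ha pigeonpea; a season-dependent ratoon effect favours perennial
  pigeonpea in dry years and perennial maize in wet years.

## Worked example

```bash
$ ppadopt run --scenario baseline --out demo
wrote trajectory.csv to demo (final adopter share 1.000)
```

The baseline (constant average yields, fixed normal season) produces the
classic S-curve: adoption passes 50% in year 7, 99.9% by year 12, and is
saturated by year 14. The trajectory CSV holds one row per year with the
season index, both systems' yields and utilities (`U_a = 3.0`,
`U_p = 4.2`, `Pa = 0.769` every year in the baseline), the three stocks, the
belief stocks and every flow.

```bash
$ ppadopt ensemble --scenario conformity --iterations 200 --seed 1 --out demo
wrote ensemble.csv to demo (mean final adopter share 0.340)
```

With stochastic seasons and yields *and* doubled social pressure (conformity,
disadopter communication rate, disadopter persuasiveness), mean adoption
collapses to 34% — the tipping-point interaction between climatic
stochasticity and conformity that is the model's central result. Compare the
plain stochastic ensemble (~84%) and the deterministic baseline (100%).

```bash
$ ppadopt sweep --factor fixed_season_index --grid 0.6,1.0,1.4 --out demo
            factor  value  years_to_50pct  final_share  mean_share
fixed_season_index    0.6               6          1.0    0.809380
fixed_season_index    1.0               7          1.0    0.764145
fixed_season_index    1.4               8          1.0    0.732769
```

Constant dry seasons (index < 1) adopt faster than wet ones: low maize yields
shrink the cost of intercrop competition while the ratoon effect favours
pigeonpea, showcasing the perennial system where conditions are marginal.

`ppadopt scenarios` lists all named experiments (baseline, stochastic,
grazing, shock, conformity, …); `ppadopt scan` runs the full-factorial
tipping-point scan over the three social factors. Everything is equally
accessible from Python:

```python
from ppadopt import fixture_config, run_simulation
traj = run_simulation(fixture_config("shock"))   # utility gap 1.2 -> -1.0 at year 10
print(traj.frame[["year", "adopter_share"]].tail())
```

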