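# causalworlds

Which state *caused* Biden to win the 2020 U.S. presidential election?
People answer questions like this effortlessly, singling out Pennsylvania or
Georgia while ignoring California — even though every won state contributed
electoral votes.  `causalworlds` implements, as a reusable pipeline, the
computational account that such causal selections track a **counterfactual
effect size**: across possible ways the election could have gone, the
standardized causal effect of winning a state on winning the presidency.

The package is aimed at computational cognitive scientists studying causal
judgment: it turns forecast-style simulation ensembles (tens of thousands of
simulated election nights, each a complete per-state outcome) into
counterfactual samplers, computes six measures of actual causal strength per
state, and provides the statistics needed to compare those measures against
human causal ratings — plus a synthetic-data generator so the whole pipeline
is testable without any downloads.

## The measures

For a world ensemble with per-state binary outcomes `S` and derived
presidency outcome `P` (electoral-vote threshold rule, 270 of 538):

* **CESM** (counterfactual effect size): for each simulation build a *twin*
  in which the focal state's outcome is resampled from its marginal
  probability `Pr(S)`, everything else held fixed; average `ΔP/ΔS` over the
  twins that actually changed, and multiply by `σ_S/σ_P`.  Behaves like the
  correlation of `S` with `P`, but zeroed for associations an intervention
  cannot produce.  A variance-free expectation form is provided alongside
  the sampled form.
* **Necessity–Sufficiency (NSM)**: `1{necessary} + Pr(S) ·
  sufficiency`, where sufficiency is the fraction of (state lost, presidency
  lost) simulations in which forcing a win in the state would have flipped
  the presidency; states with fewer than 10 qualifying simulations get no
  score.
* **Pivotality**: `1/(1+k)` where `k` is the minimal number of *other*
  states that must flip before the focal state becomes outcome-pivotal
  (computed by dynamic programming over reachable vote totals).
* **Delta-P** (observational): `P(P=1|S=1) − P(P=1|S=0)`.
* **PNS / interventional Delta-P**: the same contrast under forced
  interventions within each world.
* **Power-PC**: Delta-P rescaled by `1 − P(P=1|S=0)`.

## Worked example

```python
import causalworlds as cw

spec = cw.forecast_2020_spec(seed=11)          # 2020-style latent-probit preset
ens  = cw.simulate_forecast(spec, 50_000)       # 50k correlated election worlds
actual = cw.presets.actual_world_2020(ens.map)  # the 26 states Biden won
table = cw.score_all(ens, actual)               # 26 x 6 score table
print(table.loc[["GA", "PA", "CA", "VT"], ["cesm", "nsm", "pivotality"]].round(3))
```

```
       cesm    nsm  pivotality
unit
GA    0.074  0.184       0.500
PA    0.120  0.268       0.500
CA    0.066  1.185       1.000
VT    0.003  0.013       0.333
```

The counterfactual effect size puts competitive, vote-rich Pennsylvania and
Georgia at the top and safe little Vermont at the bottom, while ranking safe
California only mid-pack despite its 55 electoral votes — California rarely
varies across worlds, so its outcome barely correlates with the presidency.
Necessity–Sufficiency and Pivotality instead put California first (it is the
only necessary state, and it is exactly pivotal).  Regressing each measure's
scores on prior win probability and electoral votes makes the difference
quantitative: CESM weights probability over votes (standardized betas
−0.65 / 0.39 on the 50k-world preset), NSM and Pivotality do the reverse
(−0.07 / 0.87 and −0.04 / 0.92).

The full analysis sequence lives under `analysis/`:

```bash
python analysis/01_simulate.py           # synthetic ensemble + synthetic ratings
python analysis/02_score_measures.py     # the 26 x 6 score table
python analysis/03_compare_models.py     # fits, permutation tests, regressions
python analysis/04_recovery_experiment.py
```

with outputs under `results/`.  The same stages are available as a CLI
(`causalworlds simulate|score|compare|recover`), which also reads real
forecast files (wide vote-share CSV, binary CSV, or the simmed-maps JSON
layout) via `--simulations`/`--dialect`.

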