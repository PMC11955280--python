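# lynxmark

Integrated survival analysis for monitored Eurasian lynx (*Lynx lynx*)
populations: a multi-state live-encounter / dead-recovery model combined
with a recovery-corrected age-at-death model, plus a synthetic-data
generator that emulates a long-term camera-trap / telemetry / carcass
monitoring programme.

## Who this is for

Wildlife demographers estimating **true** (emigration-corrected) annual
survival of elusive carnivores from heterogeneous long-term monitoring
data: individually identified camera-trap pictures, telemetry fixes, live
captures, and carcass recoveries. The package provides the preprocessing
rules (lynx-year occasion grids, age-class assignment, single-flank
pseudo-individual resolution, censoring at translocation), the model, the
fitting machinery, and derived demographic summaries.

## The model

**States.** Each individual occupies one latent state per capture
occasion. With two connected subareas plus "outside" there are 7 states —
alive in subarea 1/2/outside, died-this-interval in each area, and an
absorbing silent "dead before" state; a single-area population uses the
5-state analogue. Occasions are 2-month (or 1-month) intervals within a
*lynx year* (1 May – 30 April).

**Transitions.** Mortality happens before movement inside each interval,
so a carcass can only be recovered where the animal started the interval.
With interval survival `s = S^(1/K)` (K intervals per lynx year) and
movement probabilities `m`, the alive-in-subarea-1 row of the transition
matrix is

```
[ s(1−m12−m13),  1−s,  s·m12,  0,  s·m13,  0,  0 ]
```

Emigration to "outside" is permanent. Annual survival is modelled on the
logit scale with sex × age-class × subarea intercepts and a normal lynx-year
random effect: `logit S = b0[sex, age] + σ_S γ_year`, `γ_year ~ N(0,1)`.

**Observations.** Alive animals are detected with probability `p`
(logit-linear in systematic and opportunistic monitoring effort, telemetry
status, and a normal individual random effect); died-this-interval animals
are recovered with probability `r` (sex × age intercepts with additive
subarea offsets). The likelihood marginalizes the latent states with the
forward algorithm, conditioning on the state at first capture, and
marginalizes unknown sex over the sex ratio ψ.

**Age-at-death model.** Carcasses with known birth year give whole-year
ages at death `j = 1..18`. Conditional on dying and being found within 18
years, `θ_j ∝ s_1 ⋯ s_{j−1} (1−s_j) r_j / P`, where `P` is the probability
of dying *and being found* within 18 years — the multi-state model's
recovery probabilities correct the classic equal-recovery assumption. The
integrated model shares the sex/age survival parameters between both data
sources.

## Worked example

```python
from lynxmark.experiments import recovery_config
from lynxmark.simulate import simulate_population
from lynxmark.inference import FitConfig, fit

cfg = recovery_config()            # one-area, monthly, 150 individuals
sim = simulate_population(cfg, seed=1)
ds, report = sim.to_dataset()
res = fit(ds, sim.spec, FitConfig(mode="mle", seed=1),
          age_records=sim.age_records)
print(res.survival_table().round(3))
```

prints

```
  subarea sex age_class  S_mean  S_q2.5  S_q97.5
0  inside   F  juvenile   0.163     NaN      NaN
1  inside   F  subadult   0.770     NaN      NaN
2  inside   F     adult   0.757     NaN      NaN
3  inside   M  juvenile   0.314     NaN      NaN
4  inside   M  subadult   0.852     NaN      NaN
5  inside   M     adult   0.716     NaN      NaN
```

The generating truth is juvenile 0.30, subadult 0.84, adult 0.76 for both
sexes: adult survival (many animal-years) is recovered closely, while
juvenile estimates are noisy at this population size — mirroring the wide
juvenile uncertainty typical of real monitoring data. `mode="mcmc"`
samples the full posterior and fills in the 95% interval columns, r-hat
and effective sample sizes.

The same flow runs from the shell:

```
lynxmark simulate --config sim.yaml --seed 1 --out data/
lynxmark preprocess --data data/ --out prep/
lynxmark fit --data data/ --mode mcmc --seed 1 --out results/
lynxmark report --fit-dir results/
```

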