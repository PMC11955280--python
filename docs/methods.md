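# Methods

## The estimation problem

Long-term monitoring of reintroduced lynx populations produces five kinds
of records — systematic camera-trap sessions, opportunistic pictures,
chance observations, telemetry fixes, live captures — plus carcass
recoveries. No single source supports survival estimation on its own:
pictures confound death with emigration and non-detection, and carcasses
alone cannot separate mortality from recovery effort. The package
implements a joint model of all sources on a common occasion grid.

## Occasion grid and data preparation

A *lynx year* runs 1 May – 30 April, matching the reproductive cycle.
Occasions are half-open 2-month (or monthly) intervals within lynx years;
every in-window date belongs to exactly one occasion. Age classes —
juvenile (first year of life), subadult (second), adult (third onwards) —
advance at lynx-year boundaries; animals with unknown birth year count as
adults from first detection, a deliberate choice that misclassifies some
subadults but avoids the larger bias of excluding them.

Cleanup rules, each logged in the preprocessing report:

- **Single-flank pseudo-individuals.** Identification from pictures
  requires matching left and right coat patterns; unmatched sides appear
  as "L-" and "R-individuals". The smaller single-flank group is deleted
  entirely (ties delete the left group — declared, deterministic). Every
  both-flank individual is always retained.
- **Single outside record.** An individual detected outside the study
  population exactly once, between inside detections, is treated as having
  stayed inside; that record is blanked.
- **Translocation.** Histories are censored at the translocation
  occasion; an animal whose first record *is* the translocation capture is
  excluded.
- Detection and recovery colliding in one occasion codes the occasion as
  the recovery (death is terminal). Detections in two subareas within one
  occasion take the chronologically last subarea; the conflict is logged.

## Process model

States cross location with status. Two-subarea layout (7 states): alive in
subarea 1 / 2 / outside, died-this-interval in each, dead-before
(absorbing, silent). One-area layout (5 states): alive inside/outside,
died inside/outside, dead-before. Mortality precedes movement within an
interval, so the died-this-interval destination is always the origin area
and recovery location identifies where the animal last lived. Emigration
to outside is permanent.

Interval survival is `s = S^(1/K)` with `K` = 6 or 12 intervals per lynx
year. Linear predictors (logit link):

- survival: `b0[subarea, sex, age] + σ_S[subarea] γ[subarea, year]`, year
  deviates standard normal; outside survival is a single overall mean
  (sparse data, not of interest). The one-area layout uses age-specific
  `σ_S[age] γ[age, year]` instead.
- detection: `a0[area, sex, age, telemetry] + a1·systmon +
  a2·(oppmon − 1) + σ_p ε_individual` inside the study population;
  intercept-only outside. The telemetry intercept is tied across sex and
  age; in the one-area monthly layout collared animals are detected with
  probability 1 (they are located every month). `systmon ∈ [0,1]` is the
  systematic-session indicator averaged over the subarea and occasion;
  `oppmon ∈ [1,3]` scores opportunistic effort per area and year and is
  centred at its baseline level 1, so intercepts refer to passive
  monitoring. Effort slopes are shared between subareas; subarea 2's
  predictor includes the oppmon and individual terms (the design is
  symmetric between subareas; configurable off).
- recovery: `d0[sex, age]` with additive subarea offsets `d_{1,2}`,
  `d_{1,3}`.

Unknown sex (about half of pictured animals in real data) is a two-point
mixture over the sex ratio ψ; known-sex animals contribute the
categorical term `log ψ_sex`, which is what lets the data inform ψ.

## Likelihood

The forward algorithm marginalizes latent states, conditioning on the
state at first capture (`z_first = y_first`); no entry process is
modelled. Occasions before first capture are skipped, not treated as
non-detections. Per-occasion normalization constants accumulate in log
space, so histories hundreds of occasions long with probabilities at
1e-12 stay finite. A transparent per-history implementation and a
vectorized dataset-level implementation (optionally compiled with numba)
are both kept; the tests verify they agree with each other and with
exhaustive path enumeration on short histories.

## Age-at-death model and integration

Known-age carcasses are categorical over ages 1..18 (18 = the documented
maximum lifespan; year 1 = juvenile survival, year 2 = subadult, years
3–18 = adult, constant). The recovery-corrected form is

    θ_j = s_1 ⋯ s_{j−1} (1 − s_j) r_j / P,
    P   = (1−s_1) r_1 + s_1 (1−s_2) r_2 + s_1 s_2 (1 − s_3^16) r_3,

where `P` uses the identity `(1−s₃)(s₃^16−1)/(s₃−1) = 1 − s₃^16`, which is
exact also at `s₃ = 1`. With constant `r` the correction cancels and θ
reduces to the classic equal-recovery form. The integrated model shares
sex/age survival between both likelihood components; recovery
probabilities entering θ are the multi-state `r` averaged over inside
subareas (equal weights by default, caller-supplied weights — e.g. carcass
counts — supported).

## Priors and inference

Normal(0, 1.5²) on intercepts, normal(0, 0.5²) on covariate coefficients
and subarea offsets, half-t(scale 1, df 2) on σ_S and σ_p (a standard
weakly-informative choice for hierarchical scales; the scale is
configurable), uniform on each movement simplex `{m_a + m_b ≤ 1}`, flat
Dirichlet on ψ.

MCMC runs an affine-invariant ensemble sampler on an unconstrained
reparameterization (log for σ, multinomial-logit for movement pairs,
logit for ψ) with differential-evolution moves, initialized near a short
penalized-likelihood optimum. Walkers serve as chains for split-r-hat and
ESS; any r-hat above the configured limit flags the fit as non-converged
rather than failing silently. Weakly identified nuisance blocks (outside
detection per sex × age, rare movement cells) mix slowest and dominate the
worst-case r-hat at reduced chain lengths; survival intercepts mix much
faster. Unknown sex is marginalized rather than sampled — mathematically
identical to a latent categorical variable and smoother for the sampler.

MLE mode maximizes the data log-likelihood with L-BFGS-B on the same
unconstrained scale (bounds ±15 keep boundary parameters finite); when
random effects are active their prior terms are included, making it a MAP
over those blocks. Datasets with no recoveries and no carcass records
flag the recovery parameters as unidentifiable.

## Synthetic data

The generator emulates the monitoring programme: cohorts of juveniles,
subadults, and unknown-birth-year adults enter each lynx year; latent
states evolve by the transition model; detections, telemetry windows,
systematic winter sessions (60-day sessions every 2–4 years, expressed as
occasion fractions), opportunistic-effort scores, carcass recoveries,
translocation censoring, and an independent corrected-θ carcass sample
are all drawn from the model. Default magnitudes mirror a reintroduced
Alpine-type population over 25 years: adult annual survival ≈ 0.78,
juvenile ≈ 0.3, per-occasion detection 0.1–0.4, recovery 0.1–0.3, about
half of pictured animals of unknown sex. Flank degradation splits a
fraction of camera-only individuals into left/right pseudo-individuals
(recovered or handled animals are always matchable and are never split).

What the generator does **not** emulate: spatial home ranges, litter
structure, density dependence, immigration, individual survival
heterogeneity, or misidentification. Passing recovery tests therefore
demonstrates correctness of the estimation machinery under the model's
own assumptions, not robustness to their violation in field data.

## Verification experiments and problem sizes

- *Parameter recovery*: one-area monthly grid, 3 lynx years (36
  occasions), 150 individuals (20 juveniles, 10 subadults, 20 adults per
  year), truth S = 0.30/0.84/0.76, detection 0.35, integrated with a
  60-carcass known-age sample. ML point estimates across 20 replicate
  seeds recover pooled adult survival with mean absolute error well under
  0.05; MCMC 95% intervals (pooled-sex adult survival) cover the truth.
  The carcass sample is included because the death-versus-emigration
  separation is weakly identified from 150 encounter histories alone —
  precisely the motivation for the integrated model.
- *Flank-deletion sensitivity*: 6-year one-area 2-month grid with
  juvenile-rich cohorts; 25% of camera-only individuals split. Deleting
  the minority flank group raises the juvenile survival estimate relative
  to keeping all pseudo-individuals (direction checked, magnitude ≈ +0.01
  at this scale). The effect requires the matched majority to anchor the
  detection rate; with most individuals split, the detection intercept
  rescales and the bias disappears.
- Oracle checks: forward likelihood vs. exhaustive enumeration (≤ 4
  occasions), closed-form P vs. 18-term sums, cohort simulations at 10⁶
  for θ and mean survival time.

## Derived quantities

Annual survival per lynx year is the inverse-logit of the intercept plus
the scaled year deviate (identical to multiplying the K interval
survivals). Mean survival time of independent lynx (subadults and adults
pooled) is the truncated discrete life expectancy from the start of the
second year of life, `Σ_{j=2}^{18} Π_{k=2}^{j} s_k`, capped at 17
additional years; the formula is this package's declared convention.
Annual emigration is `1 − (1 − m)^K`, ignoring within-year mortality
competition (declared simplification).

## Known limitations

- The sampler's reduced default settings flag slow-mixing nuisance
  parameters honestly; production analyses should raise warmup/draws.
- Adult survival is constant over ages 3–18 (no senescence).
- The age-at-death sample is assumed independent of the encounter
  histories; shared individuals would double-count information.
- MLE interval columns are not filled (no curvature-based intervals);
  use MCMC for uncertainty.
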