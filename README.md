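# registercr

Capture-recapture estimation of **over-coverage** in population registers.

Over-coverage arises when people who are officially registered as residents
have in fact left the country (or died abroad) without the event being
recorded. The registered population then overstates the true one, which
distorts denominators of demographic rates — especially for migrant
populations, whose mobility makes silent emigration common. The widespread
*register-trace* rule ("you are present in a year iff you appear in at
least one administrative register that year") treats every quiet year as
absence and therefore over-states over-coverage, most severely for newly
arrived migrants who are not yet visible in many registers.

`registercr` instead follows each registered individual longitudinally
through a Bayesian multistate capture-recapture model and estimates, for
every person and year, the posterior probability of actually being in the
country given their whole history.

## The model

For individual *i* in year *y*, a latent state Z ∈ {PRESENT, ABSENT, DEAD}
evolves as a Markov chain from the (certain) PRESENT state in the
registration year *rᵢ*. Writing xᵢᵧ for the covariate vector (intercept,
sex, age, country-of-birth group in 7 classes, time since first migration):

- survival: φᵢᵧ = P(alive in y | alive in y−1), logit φᵢᵧ = xᵢᵧᵀβ_φ
- staying: ψᵢᵧ = P(present | present in y−1, alive), logit ψᵢᵧ = xᵢᵧᵀβ_ψ
- return: ηᵢᵧ = P(present | absent in y−1, alive), logit ηᵢᵧ = xᵢᵧᵀβ_η
- de-registration: λᵢᵧ = P(notified emigration | left in y), logit λᵢᵧ = xᵢᵧᵀβ_λ
- detection: θᵢᵧₗ = P(seen in list l | present), logit θᵢᵧₗ = xᵢᵧᵀβ_o⁽ˡ⁾

so Zᵢᵧ | Zᵢᵧ₋₁, alive ~ Bernoulli(Zᵢᵧ₋₁ψᵢᵧ + (1−Zᵢᵧ₋₁)ηᵢᵧ). Deaths in the
country are always recorded; de-registrations reveal absence until a
recorded re-registration; detections force presence. Every coefficient has
an independent N(0, 2) prior.

Rather than sampling one latent indicator per person-year, the latent
states are **marginalized exactly** by a forward recursion over the three
states, and per-year presence probabilities Ẑᵢᵧ come from forward-backward
smoothing. MCMC (blocked adaptive random-walk Metropolis with a
Laplace-preconditioned global move) then targets the coefficient posterior
directly. Over-coverage for any subgroup D_y is

    OC_y = 1 − Σ_{i∈D_y} Ẑᵢᵧ / |D_y|,

with D_y the individuals administratively registered in year *y* (arrived,
not recorded dead, not de-registered without return) and Ẑᵢᵧ = 1 for
anyone detected that year.

## Worked example

```python
import numpy as np
import registercr as rc

# a synthetic register panel: 2003-2016 window, 4 detection lists,
# Swedish-style arrival cohorts with known ground truth
spec = rc.SimulationSpec(n_individuals=2000)
cohort = rc.simulate_cohort(spec, seed=7)

model = rc.RegisterCRModel.from_cohort(cohort)
res = model.fit(n_iter=2000, burnin=800, thin=4, n_chains=2, seed=7)

print(res.summary().loc[["psi.intercept", "lambda.intercept"]].round(3))
oc = res.overcoverage(credible_intervals=False)
print(oc[(oc.year == 2010)].round(4).to_string(index=False))
print("true OC 2010:", round(rc.true_overcoverage(cohort, 2010), 4))
```

Output from this exact script:

```
                   mean     sd  ci_0.025  ci_0.975   rhat
parameter
psi.intercept     1.996  0.146     1.713     2.291  1.005
lambda.intercept -0.353  0.270    -0.892     0.186  1.002
 year         method  estimate lower upper  n_registered
 2010          model    0.0554  None  None          1088
 2010 register_trace    0.0781  None  None          1088
true OC 2010: 0.0533
```

The model-based estimate (5.5%) sits close to the simulated truth (5.3%)
while the register-trace rule overstates it (7.8%), because individuals who
are present but quiet in every list are counted as absent by the trace
rule. `res.gap_summary()` tabulates the presence posteriors of undetected
person-years by the length of the unseen gap: probabilities stay high
after a single quiet year but collapse toward zero after 3-4 years unseen.

A command-line pipeline wraps the same steps:

```bash
registercr simulate --spec spec.yaml --out data/ --seed 1
registercr fit --data data/ --chains 2 --iter 15000 --burnin 5000 \
    --thin 10 --seed 1 --out draws/
registercr estimate-oc --data data/ --draws draws/ --out oc.csv
registercr diagnose --draws draws/
```

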