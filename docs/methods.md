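# Methods

This note documents the model implemented by `registercr`, the synthetic
data generator used to validate it, and the numerical and design choices a
maintainer should know about.

## Model

Each registered individual *i* carries a latent yearly state in
{PRESENT, ABSENT, DEAD}. The state is PRESENT with certainty in the
registration year rᵢ. For later years, the transition is factorized in two
stages: survival is resolved first (probability φᵢᵧ of surviving year y
given alive in y−1), then movement among the living — a PRESENT individual
stays with probability ψᵢᵧ, an ABSENT individual returns with probability
ηᵢᵧ. DEAD is absorbing. All five probability families (φ, ψ, η, λ and the
per-list detections θ⁽ˡ⁾) are logistic in a shared covariate vector
(intercept, sex, age, country-of-birth group, time since first migration),
and every regression coefficient gets an independent N(0, 2) prior; the
prior parameter is a variance, not a precision.

The observation layer for each year is:

* **detections** — a PRESENT individual appears in list *l* with
  probability θᵢᵧₗ, independently across lists; an ABSENT or DEAD
  individual appears in no list. Seeing a person in any list therefore
  pins Zᵢᵧ = 1.
* **de-registration** — on the year a PRESENT individual becomes ABSENT,
  an emigration notification is recorded with probability λᵢᵧ. A recorded
  de-registration pins the state to ABSENT until a recorded
  re-registration, which is assumed to happen with certainty on re-entry
  of a de-registered person. Silent emigrants generate no event and their
  return is detectable only through later list appearances.
* **death** — deaths in the country are recorded with probability one. We
  resolve the ambiguity of the death year by recording a death in year y
  exactly when the year-(y−1) state was PRESENT; deaths from ABSENT are
  silent and the individual enters DEAD unobserved. This keeps the state
  space a proper Markov chain while preserving the assumption that
  in-country deaths are always registered.

Events are structural: they enter the likelihood through the emission
terms and through a known-state mask (FORCED_PRESENT / FORCED_ABSENT /
FORCED_DEAD / FREE per individual-year), not as detection lists.

One modelling consequence of the mask: a de-registered person who never
re-registers is held ABSENT to the end of the window, although they could
in truth have died abroad. This slightly conditions survival on remaining
alive while abroad; it does not touch over-coverage, because unresolved
de-registrations are excluded from the denominator anyway.

## Likelihood and presence posteriors

The per-individual marginal likelihood sums the latent paths out with a
forward recursion over the three states; emission terms depend on the
(previous, current) state pair, so the recursion propagates
transition-times-emission matrices. The recursion is carried in scaled
probability space — the state vector is renormalized every year and the
log normalizers accumulated — which is algebraically equivalent to a
log-space recursion and handles exact-zero emission probabilities (an
impossible record simply yields −∞) without special-casing. Presence
posteriors Ẑᵢᵧ = P(PRESENT | whole record, β) come from forward-backward
smoothing; masked years are returned exactly 1 or exactly 0.

A brute-force oracle (`brute_force_loglik`,
`brute_force_state_posterior`) enumerates every admissible latent path
and is used only in tests; it refuses records with more than 12 free
years. The forward recursion agrees with it to better than 1e−10.

## Posterior sampling

The latent states never appear in the sampler: MCMC runs on the
marginalized coefficient posterior. The kernel composes, per iteration:

1. a random-walk Metropolis sweep blocked per linear predictor (φ, ψ, η,
   λ, one block per detection list), proposal scale tuned toward a
   0.2–0.4 acceptance rate during burn-in only;
2. one global move. When a Laplace approximation of the posterior is
   available (the default), this is an *independence* proposal from
   N(mode, 1.44·H⁻¹); otherwise it is a joint random walk with a
   covariance adapted during burn-in.

The Laplace approximation uses an analytic score: the gradient of the
marginal log-likelihood is assembled from pairwise transition posteriors
(forward-backward), i.e. each Bernoulli log-term's derivative weighted by
the smoothed probability of the transition it attaches to. The mode is
found by L-BFGS and the Hessian by central differences of that score. The
score is verified against finite differences in the tests. Chains start
at the mode plus a small preconditioned jitter. Because adaptation is
frozen after burn-in and the independence proposal is fixed throughout,
the post-burn-in kernel satisfies detailed balance exactly.

The default protocol is 15,000 iterations, 5,000 burn-in, every 10th draw
retained, two chains. Convergence is monitored with split Gelman–Rubin
R̂ (each chain halved, the usual between/within variance ratio);
cross-checked against `arviz.rhat(method="split")` in the tests.

## Over-coverage

For a year y and subgroup D_y (registered by y, no recorded death, no
unresolved de-registration — silent emigrants stay in D_y, since they
*are* the over-coverage):

    OC_y = 1 − Σ_{i∈D_y} Ẑᵢᵧ / |D_y|

with Ẑᵢᵧ = 1 for detected years and the posterior-mean smoothed
probability otherwise. The register-trace estimator replaces Ẑᵢᵧ by the
detection indicator; since Ẑᵢᵧ ≥ 0 with equality to 1 on detected years
and both use the same denominator, the model estimate can never exceed
the register-trace one (a tested invariant).

The 95% interval reported for the model estimate is a **posterior
predictive interval for the realized over-coverage**: for each retained
coefficient draw, the unconstrained presence indicators are sampled as
Bernoulli(Ẑᵢᵧ per draw) and the resulting OC fractions quantiled. We
first implemented the interval from per-draw smoothed probabilities
alone; that interval carries only coefficient uncertainty (width ~10⁻³ at
n = 5,000) and systematically misses the realized truth, whose binomial
realization noise dominates at these sizes. Sampling the indicators
matches what a latent-variable sampler would produce and restores
calibrated coverage; the point estimate is unchanged.

`gap_summary` tabulates, for every undetected and event-free
individual-year, the posterior presence probability against the number of
consecutive unseen years, time since first migration, and whether the
person reappears the following year. The characteristic pattern — high
presence probability after one quiet year when the person reappears next
year, a collapse toward zero after 3–4 quiet years — is asserted against
the enumeration oracle in the tests.

## Synthetic data generator

The real register data this model is designed for are access-restricted,
so the generator is a first-class component: it simulates cohorts from
exactly the generative process above and returns the ground-truth latent
trajectories next to the three observable tables (individuals,
observations, events).

Default conditions mirror the motivating study design: a 2003–2016
observation window with arrivals uniform over 2003–2015 (every individual
observed at least one year after arrival), seven country-of-birth groups
with a migration mix dominated by MENA and Eastern Europe, 46% women,
adult ages at arrival (18 + Gamma(2, 6), capped at 80), and four
detection lists by default (configurable; the socioeconomic registers of
the motivating data would be L = 9). Default coefficients give ~0.98
annual survival at the reference profile, staying probabilities around
0.9 that rise with time since migration, de-registration around 0.35
(higher for Nordic/North-American, lower for Eastern-European and MENA
migrants), and detection probabilities that rise with time since
migration and are lower for women. Age enters standardized ((age−35)/10)
so that coefficients of order one are meaningful; time since migration
enters linearly by default with a categorical option.

What the generator does *not* emulate: correlated covariates (marginals
only), within-year timing of moves, list dependence beyond shared
covariates, individual heterogeneity beyond the covariates (no random
effects), and arrival-cohort composition changing over calendar time.
Passing recovery tests therefore show the estimator is correct *under the
model*, not that the model is adequate for any particular country's
registers.

A separate fixed coefficient set (`recovery_coefficients`) spanning
[−1.5, 1.5] across all predictors defines the parameter-recovery
experiments; its low survival intercept (≈0.82 annual survival) is
deliberate, so that death, emigration, return and de-registration all
occur frequently enough to be identified at moderate cohort sizes.

## Validation experiments and problem sizes

The acceptance suite runs, on one CPU:

* oracle agreement on 1,000 randomized records (≤ 8 free years) at 1e−10;
* smoothing agreement on 300 records at 1e−10 plus the gap-decay pattern;
* a 20-replicate parameter-recovery study at n = 1,400 individuals per
  cohort (6-year window, 4 lists) with the reduced MCMC protocol
  4,000/1,000/thin 5, two chains — pooled 95% CrI coverage ≥ 90%, mean
  absolute error < 0.2, split-R̂ < 1.05 for every coefficient of every
  fit. The cohort size was chosen so the full study fits a desktop test
  run; the same API runs arbitrarily larger cohorts.
* over-coverage recovery on one n = 5,000 cohort over the full 2003–2016
  window: the predictive interval covers the simulated truth in ≥ 11 of
  13 years and the register-trace estimate dominates the model estimate
  everywhere;
* prior-only sampling reproducing N(0, 2) moments.

## Numerical choices and degenerate inputs

* Logistic link saturates cleanly: overflow-safe for |x·β| far beyond 500.
* Detection log-emissions use log1p on the complement; θ exactly 0 with a
  positive indicator yields −∞ likelihood, reported as an impossible
  record rather than an error.
* Individuals with rᵢ in the final year contribute only their (forced
  present) registration-year detection terms.
* Observations contradicting events (a detection during a de-registered
  stretch or after a recorded death) are warned about at packing time,
  give −∞ likelihood per record, and abort a fit with the offending
  individual-years listed.
* Hessian eigenvalues are floored at 1e−6 before inversion; if the
  Laplace stage fails for any reason the sampler silently falls back to
  pure burn-in adaptation.
* Empty subgroup denominators return an explicit empty marker (None /
  absent row), never 0/0.
* Duplicate-record collapsing (weighting identical histories) is not
  implemented: with continuous age the duplicate rate is negligible, and
  estimator invariance under duplication is tested instead.

## Known limitations

* Identifiability of the return probability η rests on silent emigrants
  who later reappear; in small cohorts its posterior is prior-influenced.
* The Gaussian independence proposal loses efficiency if the posterior is
  far from Gaussian (very small cohorts, separation in a covariate); the
  blocked random-walk component keeps the sampler correct regardless.
* Presence posteriors for the final observation years use less forward
  information by construction (nothing after the window end); their
  point estimates remain unbiased under the model but are less sharp.
* The model assumes list detections are independent across lists given
  presence and covariates; correlated registers would need a richer
  emission model.
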