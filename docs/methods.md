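# Methods

## The multi-state model

The labour-market process is a stochastic process Y(t) on six states —
initial long-term sickness absence (LTS), work (W), unemployment (U),
recurrent sickness absence (SA), temporary out (TO), disability pension (D)
— observed on an integer day grid.  Twenty directed transitions are legal:
each of the five transient states can exit to four targets; D is absorbing;
there are no edges into LTS (a sickness spell adjacent to the initial
episode extends it rather than re-entering it) and no LTS→SA edge for the
same reason.  Everyone starts in LTS at the index day, the first day of a
sickness spell of at least 28 days whose start lies outside the buffer year.

Each transition e = (s → k) has a cause-specific hazard
λₑ(t | x) = λ₀ₑ(t)·exp(βₑ′x) on the common clock t = days since
sick-listing.  The clock is **not** reset at intermediate transitions; all
20 models share one follow-up time scale.  Covariates x are the seven
baseline categories, dummy-coded against the reference pattern (female,
50–59, wage earner, sale/service/care work, no chronic disease, no prior
sickness absence, no prior unemployment), recorded at the index day and
never updated — a prediction model cannot condition on a future pathway, so
time-varying covariates are excluded by design (the code leaves no switch
for sojourn-entry updating; adding one would only require rebuilding the
risk-set covariates at entry times).

## Register derivation

Raw data are half-open benefit spells `[start_day, end_day)` per person
plus a covariate table.  Derivation rules:

* spell types SICK/UNEMP/DISAB/TEMPOUT map to SA/U/D/TO; gaps are W
  ("work = no registered payment");
* every day at or after the first disability spell start is D, regardless
  of later records;
* the maximal sickness run starting at the index day is relabelled LTS; a
  recurrence after leaving is SA, never LTS again;
* days at or after the censoring day (age 60, emigration, death — one
  combined truncation event) are marked censored;
* prior sickness absence / unemployment are counts of maximal SA / U runs
  intersecting the 365 days before the index, binned none/one-or-more and
  none/one/two-or-more;
* the one-year outcome is the state at index + 365, or "censored" when
  truncation came first.  Censored-before-outcome persons are excluded from
  logistic fitting and from *all* validation metrics (the conservative
  reading of right truncation); their DES predictions are still produced.

## Estimation

Risk sets are counting-process records: one row per maximal sojourn in the
source state, left-truncated at the sojourn entry day, ending at the
observed transition day (event for the target state, censoring for a
competing exit) or at the last fully observed day.  The partial likelihood
is maximised with Breslow tie handling (ties are massive on a day grid)
via `statsmodels.PHReg`; the baseline cumulative hazard at the reference
pattern uses the Breslow step estimator dΛ₀(u) = d(u) / Σ_{at risk} exp(β′x)
with the at-risk rule entry < u ≤ exit.  A null fit (all β = 0) makes this
exactly the Nelson–Aalen estimator, which the test suite verifies against
an independent implementation.

Degenerate designs are handled conservatively: dummy levels with fewer
than five carriers, or with no events among carriers or among
non-carriers, are unidentifiable (the partial-likelihood maximum sits at
±∞) and are dropped from that transition's fit, acting as reference at
prediction time; a singular Hessian sheds the sparsest remaining level and
retries; transitions with fewer events than coefficients, or with
diverging estimates, fall back to the covariate-free fit with a warning.
Transitions with zero training events are removed from the simulation edge
set entirely (logged); rare-but-nonzero edges are kept, hazard and all.
The logistic baselines apply the same quasi-separation rule per dummy
level, and the near-empty "unregistered" socio-economic level is merged
into "without job" when it carries no outcome variation.

## Discrete event simulation and its oracle

Day-stepping uses the competing-exponential allocation: given increments
Δₖ for the edges out of the current state, the next state is **one**
categorical draw with stay probability exp(−ΣΔ) and exit probability
(Δₖ/ΣΔ)(1−exp(−ΣΔ)).  Per-edge independent Bernoulli draws are rejected
because they can produce two transitions in a day; the 1−exp(−ΣΔ) form
keeps the vector a valid distribution for any hazard magnitude.  The
predicted occupation vector is the day-365 pathway fraction over `n_reps`
replicates (default 10,000; Monte-Carlo SE ≤ 0.5/√n_reps per state).

Because the simulated process is a time-inhomogeneous Markov chain on the
day grid, the exact day-365 distribution is the start vector multiplied by
the ordered product of the 365 one-step matrices.  This matrix-product
oracle is exact for the discretised process and serves as the reference in
every simulation test; the generator's ground truth and the fitted models
feed the same engine through one proportional-hazards factorisation
(`base[edge, t] × mult[person, edge]`), so simulation, oracle and
generation cannot drift apart structurally.

Reproducibility: each person's replicates use a counter-based Philox
substream spawned from the root seed and the person index, so results are
independent of person ordering and of any parallel work division.

## The synthetic generator

The generator emulates the register, not any particular population: seven
covariates drawn independently from configurable margins (defaults: 60%
women; ages 11/22/29/38% across 20–29…50–59; 92% wage earners; 2.7%
chronic disease; 37% prior sickness absence; 8.1% / 16.2% with one / two+
prior unemployment episodes — the profile of a long-term sick-listed
working population); a buffer year [0, 365) holding planted prior SA spells
(14–27 days, register-length sickness yet under the long-term threshold)
and unemployment spells (20–50 days) consistent with the sampled
categories, placed in disjoint slots with work-day margins so episodes
never merge; then a follow-up trajectory from the known hazard model,
re-expressed as spells.  The initial episode's four-week minimum is a
property of the generating model itself — LTS-exit baselines are zero on
the first 27 steps — not a post-hoc filter.  Censoring is a constant daily
hazard (default 2·10⁻⁴, ≈ 7% truncated within the year).

Default generating effects plant the qualitative structure the method
should recover: prior unemployment is the dominant penalty on returning to
work (log HR −0.36 / −0.65 for one / two+), chronic disease and prior
sickness absence reduce it, men and the 40–49 group return faster, chronic
disease raises the disability hazard, younger persons move to TO more.
Baseline daily rates (≈ 10⁻⁵…10⁻²) were chosen once so the day-365 state
distribution is realistic for such a cohort (work ≈ 2/3, disability below
1%) and are not revisited.

What the generator does **not** emulate: covariate correlations (margins
are independent), calendar time and macro-economic non-stationarity within
a scenario (scenarios are independent cohorts with different generating
models, avoiding the bias of reusing one sample across periods),
benefit-code taxonomy detail, and sub-14-day registration granularity in
the follow-up (spells are emitted exactly as simulated sojourns so the
derivation round-trip is exact).  Passing tests therefore demonstrate
correctness of the machinery under proportional hazards — not predictive
performance on real registry data, where effects are weaker, correlated
and time-varying.

## Numerical and design choices

* Day grid is 0-based; spells are half-open; an exit at step t ends a
  sojourn of length t+1 days.  Transition events are dated at the day
  boundary they cross.
* `increments[t]` always means the hazard mass governing the step t → t+1;
  beyond the last observed event day increments are zero, so fitted models
  predict no transitions past the support of the training data.
* The one-step matrix rows are checked to sum to 1 within 1e−12; hazard
  increments are validated nonnegative.
* Train/validation split is a seeded permutation with
  `round(n · fraction)` training rows (default fraction 0.674).
* ΔAUC% = 100·(AUC_full − AUC_reduced)/AUC_full and
  ΔBrier% = 100·(Brier_reduced − Brier_full)/Brier_full, so positive
  values mean accuracy is lost when the variable is removed.
* AUC bands are left-closed (0.8 is "good", 0.6 is "poor").
* Each person is indexed at most once per scenario (no re-entry with a
  second qualifying episode).

## Problem sizes

Defaults used by the shipped experiments: coefficient recovery on 20,000
persons (roughly 300 estimable coefficients, ≥95% expected within 3 SE);
pipeline-level comparisons on cohorts of 2,000–6,000 persons with 200–500
DES replicates per validation person, where Monte-Carlo noise (≤ 0.035 per
probability at 200 replicates) is small relative to the planted effects;
oracle agreement checks at 10,000 replicates.  These sizes are the
package's own defaults for a desk-scale machine; all of them are plain
arguments (`n_persons`, `n_reps`) and scale up unchanged.

## Known limitations

Six binary logistic fits are not a joint multinomial model, so their
predicted probabilities need not sum to one across states (deliberate
replication of the comparison design).  The Breslow increments estimate
hazard mass, while the engine converts mass to probabilities via
1−exp(−Σ); at daily rates ≤ 0.01 the resulting discrepancy between fitted
population-average occupation and empirical frequencies is below 0.02 and
is covered by a dedicated test.  No interactions, stratified baselines, or
penalisation; no confidence intervals for AUC/Brier; continuous-time
simulation between grid days is out of scope.
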