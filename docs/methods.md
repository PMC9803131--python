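# Methods

This note documents the models implemented in `expowin`, the choices made
where the design was genuinely open, what the synthetic-data generator
does and does not emulate, and the package's numerical conventions. It
states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Scope and data model

The package estimates, for cohorts defined by sex and 5-year age group,
the share of a population exposed to each of K ordered categories of a
risk factor *over a time window* year_t..year_{t+n}, conditional on
survival to an estimation year year_a ≥ year_{t+n}. The default category
set is the six weekly-working-hours bands (inactive, 0–34, 35–40, 41–48,
49–54, ≥55 h/week). Inputs are: repeated cross-sections (year, country,
sex, age group, category, weight), two-wave rotating-panel records
carrying household number, household sequence number, sex and year of
birth, a population structure (sex × age group counts at year_t), and a
life table of annual death probabilities q(sex, age, year). All tabular
interchange is plain CSV; external transition tables are in percent,
everything internal is a proportion.

## Model 1 — prevalence trend

Per category i, cell proportions are modelled as
`proportion_i = A_i + B_i * (year - year_t)`, residuals normal. This is a
linear model *on the proportion scale*, deliberately without a logit or
beta link; the cost is that out-of-range predictions can occur and that
the K independent fits need not sum to one. Both are handled by one
repair rule applied everywhere: clamp to [0, 1], then renormalise (an
all-zero vector repairs to uniform). Estimates carry both the raw and
repaired vectors.

* Year is centred at the window's first year before fitting, so A_i is
  directly the year_t intercept (numerical conditioning; the choice of
  origin does not affect predictions).
* With several countries, the fixed part is the full
  sex × age-group × year interaction and a random intercept + year slope
  per country (`statsmodels` MixedLM; a random-intercept-only structure
  is available via `random_structure="intercept"`). Cell coefficients are
  fixed effects plus the country's BLUP.
* With one country the random effects are unidentifiable and the model
  collapses to per-(sex, age-group) weighted least squares — weighted by
  the cell's survey-weight total (`weighted=False` disables this).
* One survey year makes the slope unidentifiable and is rejected rather
  than silently fitted.
* Predictions beyond a configurable horizon (default 10 years) outside
  the training years log a warning but are returned.

On noise-free data generated from the model the fit reproduces A, B to
machine precision, and at residual sd 0.01 over 20 survey years slopes
are recovered to well within ±0.005 (the slope SE is ≈ 4·10⁻⁴ there);
both are asserted in the test suite.

## Model 2 — transition probabilities

Pseudo-longitudinal pairs are built by matching consecutive waves on
(household number, sequence number, sex, birth year); key tuples that are
not unique in *either* wave are discarded (collisions cannot be resolved
without personal identifiers), and the match rate is logged. Matched
pairs are post-stratified so that weighted margins by (origin labour
status, sex, 10-year age group) equal cross-sectional targets; the scale
factor is target mass / panel mass per cell, which reproduces the target
margins exactly (asserted to 1e−9).

Per origin category a weighted multinomial logit over the K destinations
is fitted with covariates (intercept, sex indicator, FP(age)), pivot
destination 0 (by pivot invariance the choice only relabels
coefficients, not probabilities — tested). Because `statsmodels` MNLogit
does not accept observation weights, the weighted likelihood is maximised
by an in-house Newton solver with analytic gradient and Hessian,
step-halving, an L-BFGS fallback, and a small ridge (1e−6 · Σw) fallback
under separation; convergence is declared at weight-normalised gradient
max-norm below 1e−8. The solver is cross-checked in the tests against a
brute-force grid maximiser on tiny data and against statsmodels on
unweighted data. Weights are treated as probability weights: they are
scale-invariant for point estimates; reported covariances are inverse
observed information of the weighted likelihood (a design-based sandwich
is out of scope).

Fractional polynomials: degree 1 or 2, powers from
{−2, −1, −0.5, 0, 0.5, 1, 2, 3}, power 0 meaning ln x and a repeated
power (p, p) meaning (x^p, x^p ln x). Selection is an exhaustive
lowest-deviance search over all 8 + 36 = 44 candidates (deviance =
−2 · maximised weighted log-likelihood), ties broken toward lower degree
then lexicographically smaller powers; failed candidates are skipped with
a warning. No pre-scaling of age is applied (ages ≥ 15 are safely
positive for every power). The search is a plain argmin, not a staged
closed-test procedure.

Destinations never observed from an origin receive probability 0 (the
outcome is simply absent from that origin's logit); a configurable
Laplace-style floor (default 0) can keep such transitions open. An origin
with no pairs at all predicts the identity row, with a warning. Printed
transition tables ("36.9 (33.2–40.6)" percent cells) are ingested with
point and range; rows are renormalised to sum to one (printed rows sum to
≈100% only up to rounding), and a row more than 20% away from 100% is
rejected as malformed. Transition matrices with delta-method 95% ranges
can be exported in the same layout; the `method` column records that the
ranges are delta-method, not bootstrap.

### Precision of the recovery experiment

The acceptance-level recovery experiment fits the full machinery (FP
search included) on ~50,000 pairs with origins allocated evenly and
checks every matrix cell at ages 20–60 against the generative truth at a
tolerance of ±0.02. With six origins × two sexes this leaves ≈ 4,200
pairs per origin-sex; the delta-method SE of a predicted probability
reaches ≈ 0.010–0.014 at the edge of the evaluated age range for rows
with entropy like the packaged printed table, so the maximum deviation
over ~3,000 cells would sit at 0.03–0.05 *for any estimator*. The
experiment therefore uses a high-persistence truth (diagonal ≈ 0.9, mild
smooth age effects — typical of real annual labour-market transitions),
for which the tolerance and the experiment's own sampling error are of
the same order; the experiment is run at a fixed seed and its measured
maximum error (≈ 0.015–0.02) is reported by the acceptance script. At
other seeds the maximum can reach ≈ 0.026 — the tolerance characterises
this design's precision, not a uniform guarantee.

## Model 3 — microsimulation

Step A allocates the cohort (default n = 200,000) across sex × age-group
strata by largest-remainder rounding of population shares (ties to the
lower index, so allocation is deterministic); exact ages are uniform
within the 5-year band, the open band 95+ is treated as [95, 100); initial
categories are multinomial draws from the (repaired) year_t prevalence.

Step B, per simulated year and in this order: age +1, mortality draw,
then a transition draw for survivors (the order is configurable via
`mortality_first`; the DP oracle mirrors whichever order is used —
within a stratum the two orders apply the same q's and are equivalent for
the survivor distribution). The transition draw is inverse-CDF: the unit
interval is split at the cumulative row sums and the smallest k with
u < Σ_{j≤k} p_j is taken. Transition rows are looked up at the
individual's current integer age (matrices are age-resolved; a fixed
printed matrix is age-constant). Death is absorbing; dead individuals
keep their last category and are excluded from all denominators through
the alive-at-estimation-year flag. Step C applies mortality-only years to
year_a with sequences frozen.

All uniform draws are made per year for the whole cohort (mortality and
transition vectors of length n) from a single generator seeded from the
master seed, so trajectories are independent of iteration order and
bit-reproducible; the initialisation, window and censoring stages use
separate child streams of the master seed.

Assignment rules collapse a sequence S_l to one category: `max` (the
highest category ever held — the headline definition), `max-2-consecutive`
(highest category held in at least two consecutive years; an individual
with no such category falls back to `max`), and `most-time` (modal
category, ties resolved to the higher band, consistent with the
exposure-conservative spirit of `max`). Occupational turnover is
OT_k = period prevalence / point prevalence, oriented so that
point × OT = period; categories with zero point prevalence are undefined
(NaN).

### Exact oracle

For the `max` rule, (current category, maximum so far) is jointly Markov,
so the exact distribution of max(S_l) is propagated by dynamic
programming on K² states (limits K ≤ 8, window ≤ 15 years). Within a
stratum the death probability does not depend on the category, so
mortality multiplies all state masses equally and survival is tracked as
a scalar ∏(1 − q); conditioning on survival is exact. Mixtures of strata
are aggregated with survival-weighted shares. The other rules have no
small sufficient statistic and are verified by full path enumeration on
tiny instances (K ≤ 3, window ≤ 6). The DP doubles as a deterministic
backend (`backend="dp"`) in which each stratum is represented by its
band-midpoint age (lower bound + 2), versus the uniform in-band ages of
the MC engine.

## Uncertainty and sensitivity

Printed 95% ranges convert to standard deviations as
sd = (upper − lower) / (2 × 1.959964), a symmetric-normal convention.
The parametric bootstrap redraws, independently per replicate: prevalence
vectors (clamp/renormalise repair), transition-matrix cells (clamp ≥ 0,
row renormalise; age-constant per-sex matrices, matching the
one-matrix-per-cohort convention of the printed table), and life-table
q's (clamp to [0, 1]). Draws whose repair degenerates (zero-sum vector or
row) are redrawn, capped at 10·B rejections. Correlations between a
row's cells beyond renormalisation are deliberately ignored. Each
replicate re-runs the chosen backend with a fresh child seed; the
reported point is the replicate median (the unperturbed run is written
alongside as `point_unperturbed`). With all uncertainty off and the DP
backend, the three quantiles coincide exactly — asserted.

The tornado analysis enumerates the 2³ on/off combinations of
(prevalence, transitions, life-table) uncertainty and reports, per
combination, the median over replicates × cohorts × categories of
|replicate − point| / point (cells with zero point excluded), sorted
descending. The noise-scaling experiment runs the MC backend across
cohort sizes spanning at least a decade (default 1,000–64,000, 30
replicates each) and regresses log(sd across replicates) on log(n); the
fitted slope is ≈ −1/2, the law-of-large-numbers rate, and the
experiment refuses fixtures whose estimates are numerically
deterministic. Coverage of the nominal 95% ranges on fully synthetic
truth is checked pooled over several worlds and lands around 0.90 —
inside the loose [0.85, 1.0] band the repair steps and the
independence assumption warrant.

## Synthetic-data generator

The generator builds fully known "truth" worlds so every estimator can be
validated against its own generative model:

* **Prevalence surface** — per (country, sex, age group): a Dirichlet
  intercept vector (inactive-heavy base measure) and uniform slopes
  centred to sum to zero, shrunk so the truth stays within
  [0.005, 0.995] over the year range. Linear in year by construction —
  exactly Model 1's form.
* **Transitions** — per origin, a multinomial logit in
  (1, male, a, a²) with a = (age − 45)/30, pivot destination 0, and a
  diagonal bonus (default 1.6) making stayers dominate. This lies in the
  span of FP powers (1, 2) plus intercept, so Model 2 can recover it
  exactly in expectation. The default is a mobile, printed-table-like
  world; the recovery experiment raises the diagonal bonus to 4.0 (see
  above).
* **Mortality** — Gompertz q(age) = min(1, a·e^{0.085·age}) with
  sex-specific level (female 3.1e−5, male 4.7e−5: q ≈ 0.004/0.006 at 55,
  ≈ 0.03/0.04 at 80), optional multiplicative calendar trend. Exported
  life tables extend 10 years past the truth years to cover censoring.
* **Samplers** — cross-sections draw categories multinomially per cell
  with population-proportional weights; the rotating panel draws
  households of 1–3 members, ages uniform on a configurable range
  (default 16–85), wave-2 categories from the truth transition row at the
  wave-1 age, plus configurable attrition and key collisions (duplicated
  key tuples) to exercise the matcher's discard rule. Origin categories
  follow the truth prevalence by default or can be allocated uniformly
  for recovery designs.

What it does **not** emulate: quarterly sub-annual waves (the real
pseudo-panel averages over quarters; the generator produces annual waves
directly), questionnaire structure, item nonresponse, design effects of
clustered sampling, or anonymisation noise. Passing tests therefore show
correctness of the estimation chain under its own assumptions — clean
Markov transitions, linear prevalence trends, ignorable attrition unless
explicitly biased — not robustness to real-survey pathologies.

## Numerical conventions and limitations

* Row-stochasticity is enforced at 1e−9 on matrices, 1e−12 on truth
  surfaces; proportion vectors are repaired (clamp + renormalise) at
  every boundary where invalidity can arise.
* The simulation assumes first-order Markov transitions — exposure next
  year depends only on this year's category — and a single transition
  matrix per cohort for the whole window; exposure-history dependence
  and time-varying matrices are out of scope.
* Continuous exposure metrics, deterministic microflow simulation, and
  downstream attributable-fraction computation are out of scope.
* The DP backend's band-midpoint age understates within-band mortality
  heterogeneity; the difference against the MC engine's uniform ages is
  negligible for 5-year bands but grows with band width.
* Bootstrap ranges inherit the symmetric-normal reading of printed
  ranges and the independence of perturbed cells; both are
  simplifications the sensitivity analysis quantifies but does not
  remove.
* Problem sizes in the test suite and acceptance script (cohorts of
  20,000–200,000, six-world coverage pools, 50,000-pair panels) were
  chosen so each check's Monte-Carlo error is small against its
  tolerance while the whole suite stays interactive on a single CPU.
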