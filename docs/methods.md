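# Methods

## The evaluation model

The package evaluates RRD surgery against a hypothetical no-treatment
comparator from the patient perspective. Its assumptions, in order of
consequence:

1. **Utility trajectory.** Utility rises from the pre-operative TTO
   value to the one-year value during the first post-operative year
   and then stays constant for the rest of the patient's life. The
   untreated comparator stays at the pre-operative value forever, also
   incurring no RRD-related costs. No ageing-related utility decline
   is modelled in either arm; because the decline would act on both
   arms, its net effect on the *incremental* QALYs is second-order,
   but it is a real limitation for very long expectancies.
2. **Costs.** All RRD-related direct costs (surgery, hospitalisation,
   drugs, examinations, anaesthesia, transportation and downstream
   complication management) fall within the first year and are not
   discounted. Costs are taken as already inflated to a common base
   year; no CPI adjustment is performed here.
3. **Life expectancy.** Remaining years come from an age/sex life
   table: exact rows, linear interpolation between bracketing ages,
   and a clamp to the oldest row above the table maximum (extrapolating
   a decreasing table would eventually go negative). Ages below the
   table minimum raise an error rather than guessing.

### Discounting and the first year

Future QALYs are discounted with end-of-year factors (1+r)^−t, t
starting at 1, r = 0.03/year by default. The annuity factor for n
years is Σ_{t=1..⌊n⌋}(1+r)^−t + frac(n)·(1+r)^−⌈n⌉ (fractional final
years are partial-year terms, since life tables are continuous-valued);
it is computed via expm1/log1p so that rates arbitrarily close to zero
degrade gracefully to the undiscounted value n.

How the ramp-up year enters the sum is genuinely open — "utility rises
steadily in year one" does not fix the integral's discounting — so both
conventions are implemented and selectable as `first_year_model`:

* `linear_ramp` (default): year one contributes half the gain,
  undiscounted (consistent with costs, which also fall in year one and
  are undiscounted); full gain from year two, discounted from t = 1.
* `full_gain`: the full gain from year one onward, with year one
  discounted once.

At r = 3% and L ≈ 9 years the two differ by about 5% of the QALY total.

### Bootstrap and decision statistics

Each replicate resamples n patients with replacement *jointly* for
cost and QALY gain, preserving the within-patient cost–outcome
correlation, and records the replicate mean cost, mean QALY gain and
their ratio. Choices fixed here because the convention is otherwise
ambiguous:

* The headline ICER is the **mean over replicate ratios**; the ratio
  of point means is reported alongside (`icer_of_means`). For
  right-skewed costs the two differ by a few percent.
* Replicates with a non-positive QALY mean are excluded from the mean
  ICER (the ratio is undefined or sign-flipping there) and counted in
  `n_excluded`; with cohort-level gains strongly positive this is rare
  to nonexistent.
* 95% CIs are percentile intervals (2.5/97.5) on the replicate cost
  and QALY means, with numpy's linear interpolation between order
  statistics. No interval is reported for the ICER itself — decision
  uncertainty is carried by the CEAC.
* The CEAC counts replicates with *strictly* positive net monetary
  benefit λ·ΔE_b − ΔC_b; exact ties count against the intervention.
  The default λ grid is 0–150,000 CNY/QALY in 1,000-CNY steps, and
  `wtp_at_probability` reports the smallest grid point reaching a
  target acceptability.
* Verdicts follow the WHO convention: cost-effective below 3 × GDP per
  capita, highly cost-effective below 1 × GDP (defaults: 2012 China,
  38,354 CNY, threshold 115,062 CNY/QALY; USD figures at a fixed 6.29
  CNY/USD, rounded half-up to whole dollars).

### Sensitivity battery

The standard battery varies the discount rate (0%, 5%), floats costs
+10% and QALYs −10% (individually and jointly), excludes bilateral
surgery patients, and reports analytic breakeven limits. Cost/QALY
floats are applied as deterministic multipliers to the baseline
replicate vectors: scaling every patient cost by m scales every
replicate mean by exactly m, so this is identical to re-bootstrapping
the scaled data under the same seed while keeping the float rows exact
linear images of the baseline. Discount changes and cohort filters
genuinely change the problem and re-run projection plus bootstrap
under the same seed, so rows stay comparable. Breakeven limits are
computed on the mean ICER in closed form: costs may rise by
λ/ICER − 1, QALYs may fall by 1 − ICER/λ, before the ICER reaches the
threshold λ exactly.

## The synthetic cohort generator

No patient-level data are deposited for the study population this
package targets, so the generator emulates its published summary
structure, and its defaults *are* the study conditions: n = 98; age a
two-stratum truncated-normal mixture (70s: mean 75.33, SD 2.48 on
[70, 80); 80s: 82.88, SD 1.90 on [80, 95]) with a 57/98 share in the
70s; 55% male; 68% vitrectomy; 13% bilateral; utility 0.77 ± 0.12
pre-op truncated to [0, 1]; gain 0.07 ± 0.07 added and the sum clipped
to [0, 1]; costs log-normal matched by method of moments to mean
12,992 CNY; BCVA 1.06 ± 0.50 logMAR improving 0.32 ± 0.35 by three
months and 0.53 ± 0.44 by one year, floored at 0 logMAR.

Two defaults are the package's own choices where no value is
published: the cost SD (5,300 CNY, set so the bootstrap 95% CI width
on the mean cost at n = 98 is of the published order, ≈ 2,100 CNY) and
the symptom-duration distribution (log-normal, median 5 weeks).

What the generator does **not** emulate: any covariance between cost,
utility gain and age (fields are independent by default; an optional
per-stratum gain mean reproduces the smaller gain above age 80), and
longitudinal utility trajectories beyond the two measured time points.
Passing tests on synthetic cohorts therefore validate the *machinery*
— projection, resampling, decision statistics — not the joint
distribution of any real population.

Clipping and flooring are applied after summation and bias sample
means slightly: at the default parameters the utility-gain mean loses
≈ 0.009 to the [0, 1] clip and the one-year BCVA improvement loses
≈ 0.08 to the 0-logMAR floor. Both biases are bounded analytically and
asserted in the test suite.

### The packaged life table

The national life table the target study used is not published, so the
packaged default (`default_life_table`) is an explicitly **synthetic**
table: ages 70–95 in 5-year steps by sex, values plausible for urban
China (e.g. 13.0 remaining years for a 70-year-old man, 15.5 for a
woman), strictly decreasing in age, female ≥ male throughout. It is
user-replaceable via the standard CSV (`age,sex,life_expectancy_years`).
Absolute QALY and ICER levels depend directly on this table: with the
synthetic table the default cohort yields ≈ 0.6 QALYs and an ICER near
22,000 CNY/QALY, whereas the study's own (lower) expectancies produced
≈ 0.4 QALYs and ≈ 33,000 CNY/QALY. Orderings and verdicts — older
stratum less cost-effective, verdict far below threshold, sensitivity
directions — are insensitive to the choice; absolute levels are not,
which is why the acceptance checks pin only table-independent
quantities.

An open modelling question the package resolves explicitly: QALY
projection uses the *table* expectancy, not the patient's self-perceived
expectancy from the TTO interview (the two serve different purposes —
the TTO expectancy only normalises the traded years).

## Numerical and interface choices

* Strict cohort parsing aborts on any invariant violation naming row
  and field; lenient parsing drops and logs offending rows rather than
  imputing — the analysis is cohort-mean driven and silent imputation
  would bias it. Sex is required (life-table lookup needs it).
* CSV round trips are exact: floats are written at repr precision and
  read back with round-trip parsing.
* An SD is reported as absent, not zero, for a single observation.
* Report output is deterministic: identical cohort, config and seed
  reproduce `results.json` byte for byte. Replicate vectors are
  included in the JSON as the audit trail.
* Utilities are stored at full precision; rounding (2 decimals for
  utilities, whole CNY/USD) happens only at report time.

## Problem sizes

Defaults throughout are the study conditions (n = 98, B = 1000).
Calibration tests use n = 10,000 draws (three-standard-error bands);
the enumeration oracle for the bootstrap uses a 2-patient cohort where
all 4 resamples are listable, checked against B = 10,000; end-to-end
parameter recovery estimates the generator's implied QALY truth on an
n = 60,000 cohort with an independent seed, whose Monte-Carlo error is
negligible against the bootstrap SE at n = 98.

## Known limitations

* Fieller or BCa intervals for the ICER are not implemented (the
  percentile CEAC carries the decision uncertainty instead).
* No half-cycle correction beyond the explicit first-year ramp.
* Single fixed exchange rate; no multi-currency support.
* Between-group significance testing is deliberately out of scope; the
  summaries are descriptive only.
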