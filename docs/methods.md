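# Methods

## Inference model

Each arm's 90-minute cardioversion probability *p* is given an independent
uniform Beta(1, 1) prior and updated conjugately with the arm's evaluable
full-analysis-set counts: posterior Beta(1 + x, 1 + n − x). No borrowing
across doses and no informative priors are implemented; the pooled placebo
arm receives the same Beta(1, 1) prior as each dose (an assumption, since
the prior is defined per dose — it is surfaced in reports via the config
digest rather than buried).

P(*p*_active > *p*_comparator) under independent Betas is computed by, in
order of preference:

1. closed form `1 − B(a, b + b_c)/B(a, b)` when the comparator has α = 1
   (always the case for a zero-success arm under the uniform prior);
2. an exact finite sum over the comparator's integer α (evaluated in log
   space with `betaln`; used for any posterior built from integer counts);
3. adaptive quadrature of ∫ f_active(q) F_comparator(q) dq with absolute
   tolerance 1e−10 (default), raising a numerical-failure error naming the
   achieved error rather than returning a silently degraded value.

Routes 2 and 3 are cross-checked against each other, against closed forms
and against 10⁷-draw Monte Carlo in the test suite.

Tail probabilities P(*p* > t) use the regularized incomplete beta function;
the binomial-tail identity I_t(a, b) = P(Bin(a+b−1, t) ≥ a) is enforced on
an exhaustive integer grid in tests.

## Decision rules

- Interim, with q = P(p > target 0.65): close for efficacy and open one
  ladder level down when q ≥ 0.90; close for futility and open one level up
  when q < 0.10; otherwise continue. Threshold strictness is implemented
  exactly as specified by the design (≥, <, and > 0.95 for final
  superiority).
- The ladder steps one level by default. `DesignConfig.dose_overrides`
  maps an open dose to an explicit next dose, because the monitoring
  committee could skip levels (the realized trial moved 3 → 5 mg/kg); the
  skip mechanism itself is not modeled, only made configurable. Closed
  doses are never reopened; when no dose exists in the required direction
  the trial stops with reason `LADDER_EXHAUSTED`.
- Allocation is by permuted blocks — the smallest blocks consistent with
  the stated ratios (2 at 1:1 in part 1, 3 at 2:1 afterwards). Part 2
  begins at the first dose change.
- Interim triggers are interpreted as patients randomized (both arms)
  while the dose is open: 32 while 3 mg/kg is open (16 active at 1:1,
  matching the arm's randomized count in the published flow) and 18 while
  5 mg/kg is open (12 active at 2:1). Doses beyond the explicit schedule
  default to an interim every 18 patients (`interim_interval`),
  configurable. After a CONTINUE the counter restarts for the next
  interval.

## Frequentist companions

- Within-arm intervals are exact Clopper–Pearson (beta-quantile form). The
  interval method is not stated alongside the published table; Clopper–
  Pearson is adopted because it reproduces all three printed intervals
  after nearest-integer rounding. Percent rounding is nearest integer,
  half away from zero, applied only at the reporting layer.
- Analysis sets: safety = infused; full analysis = infused with evaluable
  conversion status (no flutter at randomization, no electrical
  cardioversion inside the window). When several exclusion reasons apply,
  the flow accounting records one primary reason with precedence
  not-infused > flutter > in-window DCCV.
- Time to conversion: non-converters are censored at exactly 90 min
  (administrative censoring only); patients outside the full analysis set
  contribute nothing. The Kaplan–Meier estimate is reported as survival
  and as cumulative incidence 1 − S(t). The log-rank test uses the
  hypergeometric (tie-corrected) variance with a two-sided p-value from
  χ²₁. The published time-to-conversion p-values (0.001 and <0.0001)
  depend on unprinted event times and are not reproduction targets; the
  machinery is instead validated against lifelines on constructed
  fixtures.
- Mean ± sd conversion time is computed among converters only.

## Synthetic cohort generator

The generator emulates: Bernoulli conversion per arm (defaults 0.02 /
0.42 / 0.55 for placebo / 3 / 5 mg/kg — placebo is given a small nonzero
default because the observed 0/25 would make simulated superiority
trivially 1); conversion times from a normal truncated to (0, 90] whose
post-truncation mean and sd match the configured targets (47 ± 23 and
41 ± 24 min; the parent parameters are solved numerically, since
truncation shifts the moments); the exclusion flow at rates 3/66, 3/66,
1/66; electrical cardioversion of every evaluable non-converter with
arm-dependent success (0.88 placebo, 1.0 active); AF relapse within 5 min
and recurrence within 1 min at 2% each; sinus-rhythm status at 3 h / 24 h /
30 days at the observed arm proportions with 4% missingness (which is what
produces varying denominators); and eligibility-bounded covariates (age
truncated normal (65, 9.5) on [18, 80], weight uniform 50–110 kg, 72%
male, AF episode duration uniform 3–168 h, baseline QTcF truncated normal
(410, 22) capped at 450 ms). The placebo conversion-time law is
unobservable (no placebo converters were reported); it reuses the same
family with (45, 23) min.

The ΔQTcF series on the grid {0, 15, 30, 45, 60, 90 min, 3 h, 24 h} is
A_arm · g(t) + c(t) + ε with g a Gaussian bump (width 25 min) equal to 1
at the 45-min peak, amplitudes +37.7 / +19.4 / −1.3 ms, ε Gaussian with
sd 8 ms, and c(t) a common arm-independent offset ramping linearly from 0
after 90 min to 12 ms at 24 h. The additive common offset — rather than
folding the late behavior into g — is the package's own choice: the
reported >10 ms residual at 24 h appears in *every* arm including placebo
(a rhythm-change measurement artifact), which a purely multiplicative
A·g(t) cannot produce for a negative placebo amplitude.

What the generator does *not* emulate: correlation between QTcF excursion
and conversion, joint dependence of conversion time on covariates
(independence is assumed), pharmacokinetics, adverse events, and any
safety-driven stopping behavior. Passing parameter-recovery tests
therefore show the analysis machinery is correct under the assumed
structure, not that real data follow that structure.

`fig1_fixture()` is a deterministic 66-patient cohort hard-matching the
published flow and endpoint counts; its conversion times are symmetric
grids with exactly the reported sample mean and sd. Which arms the three
non-infused patients belonged to is not published; the fixture assigns one
per arm, consistent with the per-arm safety-set sizes.

## Simulator

One master seed; `SeedSequence.spawn` gives each replicate an independent
substream, and all seeds are echoed into the summary for exact replay.
Evaluability attrition defaults to the observed rates (3/66 not infused,
4/66 not evaluable, independent draws). Superiority rates are reported per
dose over the replicates in which the dose was tested, with binomial Monte
Carlo standard errors; the any-superiority rate under a null truth is the
design's type-I-style error (the design itself implements no multiplicity
control). An exogenous early-stop hook (`early_stop_after`) emulates
sponsor termination.

Problem sizes: the test suite uses 250–400 replicates per scenario and
cohorts of 1 000–6 000 patients for parameter recovery, sized so Monte
Carlo error bands (2–3 standard errors) make the checked properties sharp;
a 2 000-replicate operating-characteristics run completes in a few seconds
on one CPU.

## Numerical and interface choices

- Probabilities are carried at full precision end to end; percent
  formatting (including the ">99.9%" saturation) happens only at render
  time.
- Patient tables are versioned comma-separated UTF-8 with an explicit `NA`
  token and a `#` header comment; the ΔQTcF series flattens onto
  `dqtcf_<minutes>` columns. Round trips are lossless at float precision.
- Reports embed the package version, a digest of the design configuration
  and the seeds needed for replay; decision audit lines are `key=value`
  structured logs.
- Degenerate inputs fail loudly: empty arms, n = 0 intervals, zero-event
  log-rank, empty full analysis set and schema violations all raise with
  the offending field named; no partial reports are written.

## Known limitations

- The interim-evaluability rule reuses the final analysis-set definition;
  the realized trial's interim data cuts are not published, so interim
  examples are synthetic rather than reconstructions.
- Exact reproduction of the published time-to-conversion p-values is not
  possible from printed information (see above).
- The simulator's dose-skip behavior is configuration, not a model of
  monitoring-committee judgment; safety stopping is out of scope.
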