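# aftrial

Bayesian adaptive dose-finding analysis and simulation for a randomized,
placebo-controlled trial of pharmacological cardioversion of recent-onset
atrial fibrillation (AF).

The package is aimed at trial statisticians and methodologists who want to
reproduce, stress-test or extend this class of design: a ladder of doses
(2–6 mg/kg) explored adaptively with Beta–Binomial interim rules, a final
Bayesian superiority analysis of each tested dose against pooled placebo,
exact within-arm binomial intervals, Kaplan–Meier time-to-conversion curves
with administrative censoring at the 90-minute assessment window, and a
whole-trial simulator for design operating characteristics. Because
patient-level trial data of this kind are typically not public, a synthetic
cohort generator with the same statistical structure (and a deterministic
fixture reproducing the published patient flow) makes every stage testable.

## Model

Each arm's probability *p* of cardioversion within 90 min carries a uniform
Beta(1, 1) prior, updated by the arm's evaluable counts to the posterior

&nbsp;&nbsp;&nbsp;&nbsp;*p* | *x*, *n* ~ Beta(1 + *x*, 1 + *n* − *x*),

independently per arm. The design decisions are:

- **Interim** (at scheduled enrollment triggers): with
  *q* = P(*p* > 0.65 | data), the open dose closes for sufficient efficacy
  and the next dose down opens when *q* ≥ 0.90; it closes for futility and
  the next dose up opens when *q* < 0.10; otherwise enrollment continues.
- **Final**: a dose is superior to pooled placebo when
  P(*p*_active > *p*_placebo | data) > 0.95 under the independent posteriors.

P(*p*_a > *p*_c) is evaluated exactly (a finite Beta-function sum for
integer shapes, closed form when the comparator has α = 1) with adaptive
quadrature as the general fallback. Within-arm intervals are exact
Clopper–Pearson; time to conversion uses the product-limit estimator and
the tie-corrected log-rank test.

## Worked example

```sh
aftrial generate --fixture fig1 --out fig1.csv
aftrial analyze fig1.csv
```

prints

```
aftrial v0.1.0  (config 5c009c3f2c)
Randomized 66; safety set 63; full analysis set 59
Exclusions: not_infused=3, flutter_at_randomization=3, dccv_within_90min=1

Primary endpoint (cardioversion within 90 min, full analysis set):
     placebo: 0/25 (0%)  95% CI 0-14%
     3 mg/kg: 5/12 (42%)  95% CI 15-72%  P(superior to placebo) = >99.9% (superior)
     5 mg/kg: 12/22 (55%)  95% CI 32-76%  P(superior to placebo) = >99.9% (superior)

Log-rank vs pooled placebo (time to conversion):
     3 mg/kg: chi2 = 12.62, two-sided p = 0.00038
     5 mg/kg: chi2 = 18.71, two-sided p = 1.5e-05
```

Reading it: of 66 randomized patients, 3 were never infused (excluded from
the safety set) and 4 more had no evaluable conversion status (atrial
flutter at randomization, or electrical cardioversion inside the window),
leaving 59 efficacy-evaluable patients. Cardioversion occurred in 0/25,
5/12 and 12/22 patients; the exact 95% intervals round to the printed
percents; and both active doses carry a posterior probability above 99.9%
of beating placebo, far beyond the 0.95 superiority threshold. The log-rank
lines compare each dose's time-to-conversion curve with placebo's (which
has no events, so the statistic is driven entirely by the risk sets).

Design operating characteristics under an assumed truth:

```sh
cat > scenario.yaml <<EOF
p_by_dose: {2: 0.30, 3: 0.42, 4: 0.50, 5: 0.55, 6: 0.60}
p_placebo: 0.02
EOF
aftrial simulate --scenario scenario.yaml --n-reps 1000 --seed 1 --out oc.json
```

which reports per-dose superiority rates with Monte Carlo standard errors,
the dose paths taken and their frequencies, and mean total enrollment
(never exceeding the 108-patient cap).

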