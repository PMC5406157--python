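# Methods

`uticea` is a decision-analytic cost-effectiveness model of diagnostic
strategies for urinary tract infection (UTI) in acutely unwell children
under five presenting to UK primary care. Eight strategies are compared:
the general practitioner's unaided clinical judgment, three thresholds of a
coefficient-based clinical prediction score (targeting roughly 5%, 10% and
20% urine-sampling rates) and four thresholds of a simpler points-based
score (≥3 to ≥6 points). A second comparison evaluates, within the
intermediate-risk stratum, immediate treatment guided by a point-of-care
dipstick (leukocyte-or-nitrite or leukocyte-and-nitrite positivity) against
delaying treatment until the laboratory culture returns.

## Model structure

The model chains four submodels; a strategy affects outcomes only through
how it stratifies children before testing.

**Short-term decision tree (index consultation).** Children reported as
very unwell (5.0%) are referred to hospital before any sampling decision.
The remainder are assigned to a lower / intermediate / higher risk stratum
from the strategy's stratification table (counts per true UTI status;
probabilities are counts over row totals, and Dirichlet(counts + 1) draws
under PSA). Higher-risk children have a sample requested and start
trimethoprim immediately; a resistant culture triggers a prescription
change (revision call), a negative culture may trigger a stop call (7.5%),
a contaminated sample is repeated exactly once, and children who cannot
provide a sample are reviewed at two days and referred to hospital if
unresolved. Intermediate-risk children are sampled and either wait for a
positive culture (laboratory arm) or are treated immediately on a positive
dipstick with negative dipsticks falling back to the culture. Lower-risk
children are not sampled; they may receive amoxicillin serendipitously
(29.4%) when the working diagnosis is a different microbial infection.
Appropriateness means the cultured uropathogen is sensitive to the
antibiotic given. Treatment categories record the *initial* prescription's
appropriateness: a resistant immediate antibiotic is classified
inappropriate even though the prescription is corrected after a positive
culture (the correction still costs a call and speeds recovery). Delayed
treatment initiated by a positive culture is costed through routine result
handling; the revision call is charged only for changing or stopping a
prescription.

**Acute illness (nine states, one-day cycles, 21 days).** States:
asymptomatic (absorbing); symptomatic non-UTI illness; symptomatic UTI
untreated / treated-sensitive / treated-resistant / delayed-treatment
window; pyelonephritis untreated / treated; hospital. The published
description does not enumerate the states, so this set is a reconstruction
of the described dynamics and is configurable. Daily resolution
probabilities are discrete hazards of Weibull survival curves. The
antibiotic treatment effect (relative risk 0.55) is applied as the ratio of
untreated to treated daily resolution probability while the effect window
is active: treatment accelerates recovery, consistent with the qualitative
description of the model; the effect persists for seven days, after which
treated and untreated probabilities coincide. Resistant uropathogens
multiply the treated resolution probability by 0.70 (uniform 0.5–0.9).
Delayed treatment follows the untreated hazard for the first two days. All
symptoms resolve by day 21. State is evaluated at day end: a child
resolving during day *d* is asymptomatic from day *d+1*, with no half-cycle
correction. Asymptomatic days accumulate the asymptomatic occupancy;
quality-adjusted life-days (QALDs) apply per-state utilities.

**Medium term (annual cycles, 3 years).** Each year a child may present
with a recurrent UTI — probability 0.003/year without UTI history, 0.080
with history and no (or prophylactically treated) VUR, and 0.080/0.68 with
untreated VUR, the prophylaxis relative risk 0.68 returning treated VUR to
the no-VUR risk — and, independently, with a non-UTI acute illness
(0.693/year). Every presentation re-enters the strategy's diagnostic
pathway at index-consultation costs and outcomes, which is what amplifies
short-term cost differences roughly 2.9-fold over the lifetime horizon.
Each UTI episode carries a 16.4% pyelonephritic-attack risk; attack counts
accumulate (capped at four). VUR (prevalence 24% among UTI) can be detected
during any laboratory-confirmed episode via the ultrasound (sensitivity
0.44) → micturating cystourethrogram (perfect, by assumption) → prophylaxis
pathway. Cycle ordering: recurrence first, then the attack draw, then the
state update.

**Lifetime tree.** The attack-count distribution maps through the
renal-scarring step function (5.0% at zero attacks rising to 58.3% at four
or more); 5% of scarred individuals develop end-stage renal disease at a
triangular onset age (mean 13.67 years), split evenly between dialysis
(annual cost, 12.25 years survival) and transplant (one-off cost, 21.6
years); unscarred (and scarred, ESRD-free) individuals live 73 years.
Scarring without ESRD carries no cost and no utility decrement. Costs and
outcomes beyond the first year are discounted at 3.5%, year 0 undiscounted.

## Economic evaluation

Net monetary benefit = QALYs × £20,000 − cost (QALDs divide by 365.25).
Incremental NMB compares each strategy with clinical judgment on the same
parameter draw (common random numbers: one vectorised draw of all
parameters and stratification probabilities is shared by every strategy),
reflecting the paired design of a single stratified cohort and stabilising
the incremental intervals. The PSA reports both the 2.5/97.5 percentile
(posterior) interval of the per-draw iNMB and the Monte-Carlo 95% CI of its
mean; the latter is what shrinks like 1/√draws. Per-child lifetime iNMB
scales to an annual UK figure by the cohort-size constant (default
4,654,000, back-solved from the published per-child/population pairing).

Seven deterministic scenarios rerun everything with exactly one change:
(1) prevalence 10%; (2) perfect laboratory; (3) doubled treatment effect
(relative risk halved); (4) doubled UTI disutility; (5) VUR and
pyelonephritis removed from the model graph; (6) doubled scarring
probabilities; (7) doubled ESRD costs.

## Parameters, units, defaults

Evidence rows live in `src/uticea/data/default_config.yaml` as named
sampling laws: binomial counts (flat-prior Beta posteriors under PSA,
successes/trials as point estimate), log-normal odds and relative risks
(sampled on the log scale), uniform and triangular ranges, and fixed
assumptions. Where the published rounding convention differs from the raw
ratio (five rows, e.g. contamination 0.046 printed against counts 140/2619)
the config carries the printed value as an explicit `estimate` override
while the PSA samples the stated distribution. A fractional count
(9.33/2789 annual first-UTI risk) is handled as Beta(10.33, 2780.67).

Monetary values are GBP at 2014/15 prices. Printed unit costs: urine sample
£7.03 (£8.10 with dipstick), laboratory-result interpretation £2.42,
prescription-revision call £16.08. The remaining unit costs and the utility
values are not printed in the source tables; the shipped defaults are
documented, overridable choices: culture £3.19, trimethoprim course £2.07,
amoxicillin course £1.67, GP consultation £31, hospital episode £180,
ultrasound £55, MCUG £121, prophylaxis £41/year, dialysis £24,000/year,
transplant £20,000. Utilities: asymptomatic 1.0; symptomatic illness 0.942
(back-solved from the published 20.73 QALDs with 16.34 asymptomatic days);
pyelonephritis and hospital 0.87; long-run baseline 0.947 (back-solved from
the published 25.74 lifetime QALYs over 73 discounted years); dialysis
0.55; transplant 0.76.

Weibull resolution defaults: non-UTI shape 1.45, scale 4.50 days;
untreated UTI shape 1.30, scale 9.0 days (treated hazards derive from these
via the treatment-effect ratio). The non-UTI scale was calibrated once so
the strategy-level mean asymptomatic days fall in the published 16.34–16.35
band, then frozen; the synthetic-diary generator uses the same defaults so
parameter-recovery tests close the loop. The pyelonephritis hazard
multiplier (0.6) is a configurable assumption — no separate resolution data
exist for attacks.

## Synthetic data and what passing tests show

`generate_cohort` emulates the analysis cohort's statistical structure:
Bernoulli UTI status at prevalence 60/2676, per-strategy strata from the
status-conditional multinomials, conditionally independent dipstick and
laboratory results at the stated accuracies (the true dipstick–culture
correlation is unknowable from printed marginals), resistance and reflux
flags, and latent uniforms driving every downstream branch.
`simulate_patients` walks each child through the identical branch logic, so
agreement between microsimulation and cohort model (within 3 Monte-Carlo
standard errors at n = 10⁶) validates the cohort algebra, not the realism
of the generator: real children have correlated test results, covariate-
dependent resolution, and nappy-pad sampling that the generator does not
emulate. Diaries are right-censored at 14 days; `fit_weibull` maximises the
interval-censored likelihood (a day-*d* resolution is an event in
(*d*−1, *d*]), which avoids the half-day discretisation bias an exact-time
fit would inherit from daily records.

## Numerical choices and edge cases

All pipeline arithmetic broadcasts over a leading draw axis, so a 10,000-
draw PSA of all eight strategies runs in seconds. Survival underflow at
extreme Weibull scales resolves to certain next-day resolution. Attack
counts above four clamp to the four-attack scarring row. Fractional
survival years discount by linear interpolation of the annuity function.
The 2.7% of intermediate-risk children without an obtained sample skip the
dipstick and follow the review-at-two-days path; a second contaminated
sample counts as no sample. In the cohort model the review branch weights
the delayed-start group by the unconditional probability of being
unresolved at day two; the microsimulation conditions on the same latent
uniform, a difference of order 10⁻³ asymptomatic days on a sub-percent
subgroup, far below Monte-Carlo resolution at the tested sizes.

## Known limitations

The nine-state enumeration and some branch details of the original tree
are reconstructions; treatment-pathway percentages are reproduced to
within about two percentage points but are not exact. Costs and utilities
that the source tables do not print are calibrated defaults, so absolute
cost levels (e.g. lifetime cost per child) are not comparable to the
published figures — the package claims the qualitative cost-effectiveness
ordering, the diagnostic cascade, and the epidemiological outputs
(recurrences, %ESRD, life expectancy), not the absolute £ rows. Very-unwell
referral is treated as independent of UTI status, per the canonical
composition; conditioning on non-referral would shift the intermediate-
stratum UTI share from 19.3% to the published 18.8%. Pregnancy
complications, hypertension, antibiotic adverse events and societal
resistance costs are out of scope.
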