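# Methods

## Scope and accounting conventions

The package evaluates the 3-year cost consequence of operating a fracture
liaison service (FLS) for emergency-department minimal-trauma-fracture
patients aged 50+, against a usual-care comparator with no organised
post-fracture pathway. All amounts are 2015-16 Australian dollars. Internal
arithmetic is unrounded IEEE double; half-up rounding to whole dollars is
applied only when tables are rendered (`flscost.report`), so printed rows
can disagree with sums of printed cells by a dollar or two — the reporting
tolerance used throughout is ±$2.

Two accounting rules matter most:

* **Per-1000 base.** Every cohort total is divided by the *full* cohort
  size — including FLS invitees who never attended — and multiplied by
  1000. This is what makes the two arms comparable.
* **Stage attribution.** Record assessment and patient/GP contact accrue
  over all contacted patients; clinic examination/treatment and follow-up
  calls accrue only for attendees. Usual care carries refracture treatment
  costs only (base-case assumption), and never carries record-assessment or
  contact costs in any scenario, since no FLS infrastructure exists there.

All patients are assumed to survive the horizon and accrue medication
costs; no competing-risk mortality, discounting, or quality-of-life
(cost-utility) analysis is performed.

## Parameters and defaults

| Parameter | Default | Units / notes |
|---|---|---|
| FLS cohort | 515 patients, 103 attendees (20%) | observed structure |
| Usual-care cohort | 416 patients, 0 attendees | |
| Wage rate | $47.50/h | Clinical Nurse Specialist 2 award level |
| Overhead rate | 27.5% | of labor cost |
| Prescription rate | 0.6666 | of clinic attendees initiated on therapy |
| Persistence schedule | 0.50 / 0.35 / 0.25 | fraction on therapy at year ends |
| Drug cost | $1416 | 3-year, prescription-weighted, full adherence |
| Horizon | 3 years | parameterized, adherence schedule must match |
| Refracture categories | hip / vertebral / wrist / other | unit cost = national total ÷ count |
| Annual throughput | 2000 patients/year | for annualized savings |
| Non-responder care cost | $1428.82/patient | **calibrated**, see below |

**Adherence convention.** Mean adherence over the horizon is the average of
per-year mid-points between year-start and year-end persistence:
(0.75 + 0.425 + 0.30)/3 = 0.49167. This is the only simple convention under
which 103 attendees × 0.6666 × mean adherence ≈ 34 full-adherence
equivalents (≈33% of attendees), the relationship the cost table is built
on. The $1416 drug cost is treated as a full-adherence cost with the
adherence factor applied afterwards.

## Calibrated sub-components

The published cost table prints stage- and cohort-level totals but not
every sub-component. The defaults are therefore calibrated:

* **Stage labor hours** are back-solved so each stage's whole-cohort total
  normalises exactly to its printed per-1000 value ($38,143 / $42,732 /
  $239,860 / $23,018). Consumables (postage/stationery at $4.20 per
  contacted patient; telephone at $9.00 per attendee) and the clinic fee
  schedule are plausible placeholders; the fee schedule lists the real MBS
  item numbers (110, 116, 12306, 65070, 66512, 66833, 66716, 66695) with
  placeholder dollar fees. Changing any placeholder changes the implied
  labor hours, not the stage totals, which are the quantities every
  downstream result depends on.
* **Refracture unit costs.** Only the two cohort-level refracture cost
  totals constrain the category table. Default cohort category counts
  (FLS 20/19/18/20 of 77 events; usual care 22/22/21/23 of 88) were fixed,
  wrist and other unit costs set to round values ($4,000 / $13,000), and
  hip/vertebral unit costs solved from the resulting 2×2 linear system
  (≈$36,687 and ≈$10,604 per event), reproducing both printed totals
  exactly. The national totals/counts in the shipped table are synthetic,
  constructed as unit cost × count. Cohort event totals 77 and 88 are
  themselves back-derived from the printed clinical incidences (0.150 ×
  515, 0.212 × 416).
* **Non-responder cost basis.** The per-patient cost behind the
  non-responder leakage analysis is not printed and is not exactly any
  printed per-attendee figure; the shipped default ($1,428.82) is the value
  implied by the reported savings at 10/20/30% treatment rates. It is an
  explicit parameter and should be overridden when better data exist.

## Scenario machinery

* **Uptake scenarios.** Uptake *u* means a fraction *u* of the usual-care
  cohort receives clinic + follow-up care at the FLS per-attendee cost, so
  the usual-care add-on is *u*/0.20 × the FLS per-1000 clinic and follow-up
  costs (at *u* = 0.20 it equals them exactly). Refracture counts are
  unchanged by assumption.
* **Adherence sensitivity** scales the 3-year *mean* adherence
  multiplicatively (clipped at 1), not each year-end point; only the
  medication component of the clinic stage responds.
* **Non-responder leakage** adds fraction × non-attendees-per-1000 ×
  cost-per-patient to the FLS arm.
* **Annualization** is strict scaling: per-1000 saving × annual
  throughput / 1000.

## Incidence statistics

Clinical incidence is events over full cohort size. The significance test
is the closed-form Wald test on the log rate ratio of the two-group Poisson
model (se = √(1/a + 1/b), model-based), which the test suite verifies
against a maximum-likelihood Poisson regression fit (statsmodels GLM with
exposure offset) to 3 decimal places on random tables. With zero events in
either arm the Wald statistic is undefined and an exact conditional
binomial test is substituted (conditional on the total, the split is
binomial with probability proportional to exposure under the null).

## Uncertainty analysis

The PSA re-evaluates the base case for each of *n* draws (default 2000):

* cohort refracture event totals ~ Poisson(77) and Poisson(88), scaling
  each arm's refracture cost proportionally and recomputing the rate ratio;
* each stage's cost × an independent gamma multiplier, mean 1, CV 0.20.

These families are standard probabilistic-sensitivity practice
(moment-matched gamma for costs, count resampling for events); the original
study's simulation parameter file is not public, so the defaults here are
labelled calibrated-plausible and the meaningful check on the win-win
fraction (net saving *and* fewer refractures) is a bracket, roughly
0.75–0.95, rather than a point value. Under these defaults it comes out
near 0.91. Draws use one root seed with per-parameter sub-streams keyed by
a hash of the target name, so adding a distribution never perturbs the
draws of others, and identical seeds reproduce results bit-exactly.
Boundary draws (RR exactly 1 or net cost exactly 0) are classified as
non-wins; a degenerate 0/0 rate ratio (impossible with the default
distributions) would be classified as a non-win too.

## Synthetic cohorts

`flscost.simulate` generates patient-level records emulating the observable
structure of the study cohorts: ages ≥50 (normal around a median of 78,
truncated), ~75% female, uniform socioeconomic deciles, attendance
Bernoulli(0.20), prescription Bernoulli(0.6666) among attendees, nested
year-end persistence via a single latent uniform per patient, and
*per-patient refracture counts Poisson* with mean equal to the target
3-year clinical incidence — Poisson rather than Bernoulli because clinical
incidence counts events and a patient can refracture more than once.
Categories are multinomial (uniform by default; the true cohort mix is not
published) and event days uniform over the 1095-day horizon.

The generator does **not** emulate: treatment-effect mechanisms (incidence
targets are exogenous), socioeconomic confounding, seasonality or
clustering of events, loss to follow-up, or mortality. Passing recovery
tests therefore show that the pipeline's estimators are consistent with the
generator's sampling model, not that the cost conclusions transfer to any
particular real population.

A `fixed_fraction` mode makes headcounts exact (round(n × rate)) so that
deterministic end-to-end checks are seed-independent; with it, a synthetic
FLS cohort of 515 reproduces the default 103 attendees and 77 events
exactly.

## Numerical choices and degenerate inputs

* Stage totals are exact to ~1e-9 of the printed values (float back-solve);
  all printed-value comparisons in tests use ±$2 or tighter.
* Validation never fails fast: every violated invariant is collected and
  reported with its field path in one error.
* `per_thousand` rejects empty cohorts; the rate-ratio test rejects
  non-positive exposures; uniform/beta/gamma hyperparameters are validated
  at construction.
* Problem sizes: the full test suite runs in a few seconds; the PSA uses
  2000 iterations (vectorised, ~10 ms) and the recovery check 200 seeds ×
  two cohorts (~1 s). These match the scale of the analysis itself, which
  is desk-scale by design.

## Known limitations

* Sub-component defaults are calibrated, not observed; only stage and
  cohort totals are evidence-backed.
* The deterministic comparison inherits the source design's limitations:
  two non-randomised cohorts from different hospitals, no
  difference-in-differences baseline, refracture costs derived from
  national averages rather than observed billing.
* The PSA omits correlation between cost components beyond shared event
  counts, and does not model uncertainty in refracture *unit* costs
  separately from event counts (a shared unit-cost multiplier would move
  both arms nearly in parallel and barely affect the saving's sign).
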