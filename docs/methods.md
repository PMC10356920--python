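# Methods

This note documents the modelling assumptions, the defaults and why they
were chosen, the numerical conventions, and what the validation experiments
do and do not establish.

## The design being implemented

The pipeline implements a two-model nested case–control (NCC) study of
statin exposure and open-angle glaucoma (OAG) onset in a working-age
dyslipidemia cohort, operating on claims-shaped inputs: a patient table
(sex, birth year-month, enrollment span) and a dated event table in three
code systems (ICD-10 diagnoses, EphMRA-ATC prescriptions, Japanese
procedure codes).

Key conventions, applied uniformly:

- **Codes** are stored dotless and uppercase ("H40.1" → "H401"). A listed
  3-character category matches all of its subcodes (prefix semantics), and
  a range such as "I20-I25" is compared lexicographically at the endpoints'
  length. The choice of prefix semantics for 3-character categories is a
  genuine open point in claims work; it is the more inclusive reading and
  is what makes "E78" capture "E780" etc.
- **Windows** are half-open `[start, end)` everywhere, so a prescription on
  the index date itself is *not* exposure and boundary events are never
  double-counted. The confirmatory-diagnosis window is the one deliberate
  exception: it is `(entry, entry + 6 months]`, strictly after entry —
  a code on the entry date is the entry, not a confirmation.
- **Month arithmetic** is day-of-month aware (2010-01-15 → 2010-02-14 is 0
  whole months) with day clamping at short months. Month-granular inputs
  are carried as the first day of the month.
- An **outcome on the entry date** counts as prevalent disease and excludes
  the patient: cases must be strictly incident.
- An outcome occurring **after the final dyslipidemia code** falls outside
  the observation period; the patient is kept as a non-case censored at the
  final code, matching the definition of observation as "entry to the
  earlier of index date and last dyslipidemia diagnosis".

## Eligibility and attrition

Seven exclusion steps run in a fixed order (no dyslipidemia code; run-in
< 6 months; no confirmatory code; age < 20; prior outcome; prior statin
use; observation below the model's minimum follow-up of 12/24 months), and
the attrition log records each step's count so flows are comparable across
runs. Because the observation-period criterion uses the index date as its
endpoint for cases, a case whose outcome arrives before the minimum
follow-up is excluded — this is precisely what guarantees that the
exposure-assessment window of every analyzed case lies after cohort entry.

## Risk-set sampling

"At risk at the case's index" is evaluated on the *duration* scale (time
since each member's own entry): a candidate is eligible if its observation
reaches the case's duration-to-index and it is outcome-free at that
duration (a strictly later case qualifies). This is standard
incidence-density sampling; controls may be reused across sets ("with
replacement"), but a set never contains the same person twice, and up to
10 distinct controls are drawn uniformly from the pool. Matching calipers:
same sex, ±5 years of age at entry, ±3 calendar months of entry
(month-index difference, not day counts). The case's calendar index date
is transferred unchanged to its controls; since entry is matched within
±3 months and the cohort requires a 6-month pre-entry run-in, the
control's exposure window is always covered by claims history.
Determinism: cases are processed in ascending index-date order, candidate
pools are sorted by patient id, and a single seeded generator drives all
draws, making output invariant to input row order.

## Exposure and covariates

Q1/Q2 cutoffs are the 25th/50th percentiles — **nearest-rank convention**,
the value at position ⌈p·n⌉ of the sorted list, which is deterministic and
always an observed count — of in-window prescription totals pooled over
the *selected* cases and controls with at least one in-window
prescription. Pooling cases with controls mirrors the reported count
distributions, whose control-arm interquartile endpoints coincide with the
published cutoffs. Per-substance exposure applies the same cutoffs to
substance-specific counts; a patient can qualify for several substances
(multi-hot indicators, reference level "not exposed to any statin at that
threshold"), which is why per-substance exposed counts can sum to slightly
more than the any-statin count.

Comorbidity covariates require matching codes on **two distinct service
dates** within the six months before entry (duplicate same-day claim lines
are administrative artifacts, not repeat encounters); co-medications
(beta-blockers C7; steroids H2/S1B/S3B/S3C) require a single prescription
in the same window, the natural analogue when a "two visits" rule cannot
apply to dispensings. The infectious/inflammatory composite is positive
when any one of its thirteen sub-groups meets the two-date rule on its own.

## Conditional logistic regression

The matched-set conditional likelihood ℓ(β) = Σ [x₀'β − log Σⱼ exp(xⱼ'β)]
is maximized by Newton–Raphson with step-halving, log-sum-exp
stabilization within sets, convergence at gradient ∞-norm < 1e-8, and at
most 50 iterations. Standard errors come from the observed information at
the optimum; CIs use the exact normal quantile 1.959964, displayed values
are rounded to two decimals. Three degenerate regimes are handled
explicitly rather than silently:

- a term with no within-set variation anywhere carries no information: it
  is fixed at zero and reported with an infinite-variance flag;
- complete/quasi-separation is detected as a coefficient crossing ±15
  while the likelihood still improves, and raises `SeparationError`;
- sets without any variation contribute a constant and are retained but
  counted in diagnostics.

The marginal 2×2 odds ratio with its Woolf interval is provided as a
reporting utility; its agreement (to two decimals) with the matched crude
OR on the published margins is an empirical regularity of tightly balanced
matching, not an identity.

## The synthetic claims generator

The generator emulates the *structure* the analysis assumes, on a discrete
monthly grid with events dated on the first of the month:

- **Demographics**: ~60% male, age at entry ~ N(51, 8²) truncated to
  [20, 74] — chosen so generated baseline tables resemble a working-age
  dyslipidemia population (median ~51, ~60% male).
- **Enrollment and visits**: uniform calendar entry in 2005–2020; first E78
  code after a ≥6-month run-in; with probability 0.85 the patient keeps
  visiting monthly (further E78 codes) until dropout — the complement
  exercises the confirmatory-code exclusion. Independent monthly dropout
  of 0.02 gives a median observation near 32 months, the order of
  magnitude reported for this population. (No richer censoring mechanism
  is modelled; claims databases rarely reveal one.)
- **Prescribing**: statin therapy initiates within the first 3 months
  after diagnosis (treatment decisions cluster at diagnosis; monthly
  initiation probability 0.20, so roughly half of patients ever use a
  statin, matching the reported ~50%), is absorbing once started, and
  emits one fill per month with adherence probability 0.97. Substances
  follow a fixed market-share mix.
- **Comorbidities**: independent per-patient flags with prevalences near
  the reported control-arm frequencies, floored at 1% for the very rare
  conditions (hypotension, TIA) so that 15-term adjusted fits at
  simulation scale remain identified; true comorbidities emit two codes on
  distinct pre-entry months, and single-occurrence noise codes are
  sprinkled elsewhere to exercise the two-date rule. Small fractions of
  prevalent outcomes (1.5%) and pre-entry statin users (1%) exercise the
  corresponding exclusions.
- **Outcome**: discrete-time proportional hazards
  h(t) = h₀·exp(β_statin·X(t) + Σ β_c·C_c) with X(t) the on-therapy
  indicator, sampled exactly by two-segment geometric draws. The baseline
  monthly hazard defaults to 0.002 — deliberately above a realistic OAG
  incidence so that cohorts of a few thousand patients yield a few hundred
  incident cases and regression experiments are informative at that scale;
  with a realistic hazard the same experiments would simply need
  hundred-thousand-patient cohorts. The outcome emits exactly one event in
  one of the three composite channels (defaults 0.75/0.24/0.01
  diagnosis/drug/surgery, surgery rare as reported).

Randomness is organized as per-patient substreams keyed by
(seed, patient index), so enlarging a population never reshuffles existing
patients, and identical configurations are byte-identical end to end.

### What passing recovery tests shows — and what it does not

Because the hazard's exposure is "on therapy" while the analysis measures
"Q1/Q2 prescription count in the window", a recent initiator or a
low-count user is true-exposed but classified unexposed. This
misclassification attenuates the estimated OR by a few percent — visible
as mean recovered ORs slightly below the simulated hazard ratio before
small-sample effects push the other way. The null is immune (no effect to
attenuate), so type-I error calibration is clean. With ~200 cases and 15
parameters, ultra-rare covariates occasionally produce quasi-separation;
such replicates are flagged, reported, and excluded from aggregates rather
than contributing diverged estimates.

The generator does **not** model dose or adherence intensity, competing
risks, between-statin effect heterogeneity, enrollment gaps, seasonal or
calendar trends, code-assignment error, or confounding by indication
(covariates are drawn independently of prescribing). Passing recovery
tests therefore demonstrates that *the pipeline's machinery estimates what
the design says it estimates under its own assumptions* — not that those
assumptions hold in any real claims database.

## Validation experiments and problem sizes

- Null calibration: 5,000-patient cohorts, 200 replicates, adjusted model;
  Wald rejection at p < 0.05 and 95% CI coverage of OR = 1.
- Effect recovery: true hazard ratio 2.0, 5,000 patients, 100 replicates;
  mean adjusted OR.
- The conditional-likelihood implementation is checked against closed
  forms (ℓ(0) = −Σ log(1+Mᵢ), discordant-pair n₁₀/n₀₁), direct
  enumeration, finite differences, and an independent implementation
  (statsmodels' conditional logit) on 100+ random instances.
- Cohort building and control sampling are re-verified by brute-force
  per-patient oracles that share no code with the pipeline.

These sizes keep the full suite in the ten-minute range on a single CPU
while leaving Monte-Carlo error well inside the asserted bands.

## Known limitations

- Exposure thresholds depend on the realized count distribution of each
  run, so "Q1 exposure" is a run-relative, not absolute, definition —
  exactly as in the original design.
- The marginal-OR utility requires all four cells non-zero (optional
  Haldane–Anscombe +0.5 correction).
- Enrollment is a single span per patient; no gap bridging.
- The per-statin analysis fits one multi-indicator model per
  (model, quartile) rather than six separate models; with a shared
  "non-user of any statin" reference this is the cleaner formulation, and
  which variant the original analysis used is not documented.
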