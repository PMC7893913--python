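# Methods

## Scope and model

`oudmbc` implements the decision logic of a measurement-based-care (MBC)
program for office-based buprenorphine treatment of OUD as a deterministic
rules engine. The engine is decision *support*: every output is an ordered
list of alternative treatment plans ("OR" branches, in the emphasis order
of the source grid) plus alerts; it never selects a branch, and the
clinician's actual choice is read back from the trajectory record. The
unit of time is weeks since treatment initiation; calendar mapping is the
caller's concern.

Out of scope by design: TAPS internal scoring and psychometrics,
buprenorphine induction dosing, urine drug screening, comorbidity
screening, EHR integration, and any outcome prediction.

## Instruments

* **TAPS opioid gate** — `needs further assessment ⇔ heroin > 0 ∨
  rx_opioid > 0`. Records missing either opioid key are rejected: absence
  is indistinguishable from a malformed capture, not a negative screen.
* **OUD Symptom Checklist** — 11 yes/no criterion items; total = count of
  "yes" (0–11); the past-2-week opioid-use item passes through uncounted.
  Wrong item counts or missing fields are rejected, never imputed — the
  score drives treatment decisions and silent imputation is unsafe.
  Whether the "feel the effects of opioids" item should be reverse-scored
  under buprenorphine is an open field question and is not implemented.
* **PAQ-OUD** — adherent ⇔ days missed ≤ 1 (i.e. ≥ 80% of doses taken)
  and no over-taking. When both over- and under-taking are reported,
  over-taking wins so the more safety-relevant status surfaces; both facts
  stay on the record. The 11 reason codes are stable machine identifiers;
  the count is normative, display wording is not. Craving or withdrawal
  among the endorsed reasons sets the consider-dose-increase hint.

## Response classification

Percent decrease from the immutable week-0 baseline is kept as an exact
`Fraction`; with integer totals 0–11 every band boundary is exactly
representable, so no floating-point rounding can move a visit across a
band. Boundary policy: the printed bands are "< 25%", "25–75%", "> 75%",
so 25% and 75% are inclusive to the middle band — a decrease of exactly
75% without use is partial, not full. Worsening (negative decrease) falls
under "< 25%"; no extra category is invented. A baseline of 0 raises a
degenerate-baseline error: such a patient is not symptomatic and
change-from-baseline is undefined. Re-baselining after relapse is not
supported.

## Decision engine

The rules table ships as YAML (`data/rules_table.yaml`), one entry per
CDP (weeks 0–12, biweekly) and response category, and is the single
source the engine executes; the test suite holds a second, independent
transcription so the two can disagree if either drifts.

Numerical and procedural choices:

* **Floor CDP mapping.** A visit at week *w* uses the rules of the latest
  scheduled CDP ≤ *w*; beyond week 12 the week-12 rules persist.
  Escalation keys on treatment time already completed. Follow-up visits
  before week 2 are a state error — the week-0 row is initiation guidance,
  not re-assessment.
* **Full-response streak.** The state stores the week the current
  uninterrupted run of full responses began; streak = current week −
  run start. Full response at week 2, 4 and 6 therefore reaches a 4-week
  streak at the week-6 visit. Any non-full classification resets the run.
  The continuation gate (streak ≥ 4 weeks) replaces the row's branches
  with a single enter-continuation option and a 4-week revisit interval.
* **Dose ceiling.** Increase options suggest `min(current + increment,
  24)` mg and the whole branch is dropped once the current dose is at or
  above 24 mg (≥ rather than = so clinician-set doses above the ceiling
  cannot elicit an "increase" to a lower number). The increment (default
  4 mg) and initiation dose (default 8 mg) are configuration, not
  published constants — only the 24 mg ceiling and "lower end of the
  therapeutic range" are prescribed.
* **BID split.** Divides the unchanged daily dose across twice-daily
  dosing; only the frequency is emitted. When the patient already doses
  twice daily the option is kept as a flagged no-op rather than silently
  dropped, preserving the printed branch structure.
* **Non-adherence precedence.** A non-adherent visit yields only the
  address-non-adherence option, even in cells where referral would be
  mandatory: reasons for non-adherence are to be explored before any
  other change. The visit is still classified and the streak updated, and
  trial-cap alerts still attach.
* **Escalation.** Mandatory referral is exactly the minimal/nonresponse
  rows of weeks 10 and 12. The tension with the guidance that minimal
  trials "should not exceed 8 weeks" is resolved as an alert
  (minimal-response trial cap, weeks > 8), not a forced action; likewise
  partial trials > 12 weeks alert rather than force referral. Week-10/12
  partial rows list increase and counseling as separate branches, exactly
  as printed, even though earlier rows bundle them.
* **Continuation phase.** Visits re-administer the instruments every 4
  weeks. Loss of full response raises a relapse alert and returns the
  episode to clinician judgment; no continuation→acute path is defined, so
  none is automated.

All constants (ceiling, increment, cadences, band boundaries, adherence
cutoff) live in `EngineConfig`, overridable from YAML with the overridden
keys recorded for provenance. Band boundaries accept exact fractions.

## Synthetic cohort generator

The generator emulates the structure the algorithm assumes, not any
observed population: a symptomatic baseline (checklist total uniform on
6–11), three latent response classes, per-class adherence lapse rates,
optional dropout (truncation) and visit delay (off-schedule arrival, which
exercises floor-CDP mapping). Class paths: full responders cross the
>75%-decrease / no-use threshold at week 6 (configurable) after improving
through the partial band, sometimes via the large-decrease-with-use arm;
partial responders stay in the 25–75% band; nonresponders stay below a 25%
decrease with ongoing use. Item-level responses are sampled by choosing
which baseline-endorsed criteria remit, uniformly, to hit the target total
— only totals and the use flag are normative downstream. The simulated
clinician takes the first-listed branch (a choice-policy hook can
override). Default lapse/dropout rates (miss-day probability 0.02/0.05/
0.12 by class, over-taking 0.02, dropout 0.05, delay 0.1) are plausible
rates for an engaged office-based cohort, chosen once for test coverage of
the non-adherent paths.

What passing tests therefore show: the engine reproduces the printed rule
set exactly on trajectories with the assumed structure. What they do not
show: anything about real patients — the generator has no symptom
measurement noise, no partially-completed instruments, no correlation
between adherence and symptom course beyond class membership, and the
response classes themselves are unvalidated constructs.

Self-consistency: with lapse-free parameters the classifier recovers the
latent class at each patient's final visit for ≥ 99% of n = 500 simulated
patients (exact recovery by construction; the margin allows boundary
noise if paths are reconfigured). Recovery is read at the final completed
visit because full responders enter continuation at week 10 and have no
week-12 acute visit.

## Problem sizes

All checks are exhaustive where the space is finite and small: 2^11
checklist vectors, 264 classifier cases, the full (CDP × category ×
adherence × dose 2–32 mg) grid for the rules sweep, and 101 integer
percent-decrease points for the band scan. The stochastic check uses a
500-patient seeded cohort. The whole suite runs in a few seconds on one
CPU.

## Known limitations

* The decision rules are expert consensus, untested in clinical practice;
  this package makes them executable, not validated.
* Use is dichotomized (any vs none); decreasing or sporadic use is not
  distinguished from unchanged use within a band.
* Continuation-phase duration, taper and discharge criteria are undefined
  in the source material and therefore absent.
* Reason-code and checklist item wordings are machine identifiers; the
  published instrument texts live in appendices not reproduced here.
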