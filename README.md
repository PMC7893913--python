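# oudmbc — measurement-based care for office-based buprenorphine treatment

`oudmbc` is a deterministic rules engine for measurement-based care (MBC)
in the office-based treatment of opioid use disorder (OUD) with
buprenorphine. It is written for informaticists and clinical-systems
engineers who need the decision logic of an MBC program as a testable,
machine-readable library rather than prose: instrument scoring, a
change-from-baseline treatment-response classifier, and the longitudinal
clinical decision support state machine for the first 12 weeks of
treatment, plus a seeded synthetic trajectory generator so every decision
path can be exercised without patient data.

## The measures and the algorithm

**Screening.** The TAPS tool (Tobacco, Alcohol, Prescription medication,
and other Substance use) provides per-substance risk scores. The engine
applies only the opioid gate: a score > 0 on the heroin or prescription-
opioid item flags the patient for further OUD assessment. TAPS internal
scoring is published elsewhere and consumed as given.

**Symptom tracking.** The OUD Symptom Checklist asks one yes/no question
per DSM-5 OUD criterion (11 items; each "yes" = 1 point, total 0–11) plus
a past-2-week item on use of any opioid other than buprenorphine.

**Adherence.** The PAQ-OUD (Patient Adherence Questionnaire for OUD
medication) records days of missed medication in the past week, an
over-taking flag, and up to 11 endorsed reasons. Taking medication ≥ 80%
of the time — missing ≤ 1 day/week — without over-taking is *adherent*.
Non-adherence attributed to craving or withdrawal raises a
consider-dose-increase hint.

**Response classification.** With baseline checklist total *B* (week 0)
and current total *S*, the fractional decrease is Δ = (B − S)/B, computed
on exact rationals. With *u* the past-2-week use flag:

| category | rule |
|---|---|
| full response | Δ > 75% AND no use |
| partial response | 25% ≤ Δ ≤ 75% (no use), OR Δ > 75% with use |
| minimal / nonresponse | Δ < 25% (incl. worsening), OR 25–75% with use |

The 25% and 75% boundaries belong to the middle band; full response is
never assigned while use continues.

**Decision support.** Critical decision points (CDPs) fall every 2 weeks
from week 0 (CDP #1, initiation) through week 12 (CDP #7); off-schedule
visits map to the latest completed CDP, and week-12 rules persist beyond
week 12. Each visit's (CDP × category) cell of the rules table
(`src/oudmbc/data/rules_table.yaml`) yields ordered "OR" branches —
continue, increase dose (≤ 24 mg/day, the labeled ceiling), split the
unchanged dose to twice daily, add adjunctive counseling, refer to
specialty care — which are offered, never auto-applied. Non-adherence
pre-empts all of them: the only option is to explore and address it.
Full response sustained ≥ 4 weeks moves the patient to a continuation
phase with 4-weekly visits; minimal/nonresponse at weeks 10–12 makes
specialty referral mandatory, with trial-cap alerts for minimal
trials > 8 weeks and partial trials > 12 weeks.

## Worked example

A patient using heroin daily starts buprenorphine 8 mg/day at week 0 with
a baseline checklist total of 8. At week 2 the symptom total has fallen to
1 but use continues; the clinician increases the dose to 12 mg. At week 4
there were 2 days of small use; the dose is held. At week 6 the patient
reports no use.

```python
from oudmbc import worked_example_trajectory, export_visits_csv
print(export_visits_csv([worked_example_trajectory()]).to_string(index=False))
```

yields (abridged):

```text
 week  total  use_2wk category  cdp_index                                                     options  next_visit_weeks
  2.0      1     True  partial          2                               continue_dose | increase_dose                 2
  4.0      1     True  partial          3 increase_dose+add_counseling | continue_dose+add_counseling                 2
  6.0      1    False     full          4                                               continue_dose                 2
```

Weeks 2 and 4 are partial responses (an > 75% symptom decrease, but with
ongoing use), so the engine offers continue-or-increase branches; at week
6 use has stopped and the visit is classified a full response. Held for 4
weeks, that full response would gate the continuation transition.

The same trajectory runs from the shell:

```bash
oudmbc simulate --n 50 --seed 1 --out cohort.json   # synthetic cohort
oudmbc replay cohort.json --csv visits.csv          # engine over every visit
oudmbc rules                                        # machine-readable rules table
```

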