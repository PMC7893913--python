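# Machine-readable clinical decision support rules table.
#
# One entry per critical decision point (CDP), weeks 0-12 at a biweekly
# cadence. Each response-category row lists its treatment-plan branches in
# printed order; branches are alternatives ("OR") offered to the clinician,
# never auto-selected. Actions within a branch are bundled (e.g. increase
# dose AND counsel). `continuation_gate` marks full-response rows that
# redirect to the continuation phase once full response has been sustained
# for at least 4 weeks. `referral_mandatory` marks rows where referral to
# specialty care is the only plan.
#
# add_counseling = adjunctive counseling regarding behaviors that support
# recovery, including mutual help group attendance ("medical management").
# split_dose_bid = divide the unchanged daily dose in half, taken twice daily.
schema_version: "1.0"
decision_points:
  1:
    week: 0
    rows:
      symptomatic:
        branches:
          - [initiate_treatment]
  2:
    week: 2
    rows:
      full:
        continuation_gate: false
        branches:
          - [continue_dose]
      partial:
        branches:
          - [continue_dose]
          - [increase_dose]
      minimal_nonresponse:
        branches:
          - [increase_dose]
  3:
    week: 4
    rows:
      full:
        continuation_gate: true
        branches:
          - [continue_dose]
      partial:
        branches:
          - [increase_dose, add_counseling]
          - [continue_dose, add_counseling]
      minimal_nonresponse:
        branches:
          - [increase_dose, add_counseling]
          - [continue_dose, add_counseling]
  4:
    week: 6
    rows:
      full:
        continuation_gate: true
        branches:
          - [continue_dose]
      partial:
        branches:
          - [increase_dose, add_counseling]
          - [split_dose_bid, add_counseling]
      minimal_nonresponse:
        branches:
          - [increase_dose, add_counseling]
          - [split_dose_bid, add_counseling]
          - [refer_specialty, continue_dose]
  5:
    week: 8
    rows:
      full:
        continuation_gate: true
        branches:
          - [continue_dose]
      partial:
        branches:
          - [increase_dose, add_counseling]
          - [split_dose_bid, add_counseling]
      minimal_nonresponse:
        branches:
          - [split_dose_bid, add_counseling]
          - [refer_specialty, continue_dose]
  6:
    week: 10
    rows:
      full:
        continuation_gate: true
        branches:
          - [continue_dose]
      partial:
        branches:
          - [increase_dose]
          - [add_counseling]
          - [refer_specialty, continue_dose]
      minimal_nonresponse:
        referral_mandatory: true
        branches:
          - [refer_specialty, continue_dose]
  7:
    week: 12
    rows:
      full:
        continuation_gate: true
        branches:
          - [continue_dose]
      partial:
        branches:
          - [increase_dose]
          - [add_counseling]
          - [refer_specialty, continue_dose]
      minimal_nonresponse:
        referral_mandatory: true
        branches:
          - [refer_specialty, continue_dose]
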