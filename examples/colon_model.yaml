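# Recursive path system for the colon-cancer worked example:
# affluence (0-1 metric) -> emergency admission and hospital caseload
# (linear probability equations) -> discrete-time logistic hazard of death.
exposure: affluence
outcome:
  time: time
  event: event
  J_max: 24
  baseline: constant
  proportional: true
equations:
  - dependent: emergency
    regressors: [affluence, age10]
    link: linear
  - dependent: caseload
    regressors: [affluence, age10, emergency]
    link: linear
  - dependent: hazard
    regressors: [affluence, age10, emergency, caseload, stage2, stage3, stage4, treatment]
    link: discrete_time_logit
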