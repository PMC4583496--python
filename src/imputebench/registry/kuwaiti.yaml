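# Kuwaiti risk model: age bands, sex, family history, treated
# hypertension.  placeholder_coefficients: replace with the published
# values before substantive validation.
name: kuwaiti
intercept: -3.6
link: logistic
placeholder_coefficients: true
terms:
  - variable: age
    transform:
      band:
        breaks: [35.0, 45.0, 55.0, 65.0]
        scores: [0, 1, 2, 3, 4]
    coefficient: 0.45
  - variable: sex          # 1 = female
    transform: {indicator: 1}
    coefficient: -0.25
  - variable: fh_mother
    transform: identity
    coefficient: 0.35
  - variable: fh_father
    transform: identity
    coefficient: 0.35
  - variable: bp_meds
    transform: identity
    coefficient: 0.60
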