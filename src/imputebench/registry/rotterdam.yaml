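# Rotterdam predictive model 1: age, sex, BMI, antihypertensive
# medication.  placeholder_coefficients: replace with the published
# values before substantive validation.
name: rotterdam
intercept: -6.5
link: logistic
placeholder_coefficients: true
terms:
  - variable: age
    transform: identity
    coefficient: 0.06
  - variable: sex          # 1 = female
    transform: {indicator: 1}
    coefficient: -0.40
  - variable: bmi
    transform: identity
    coefficient: 0.07
  - variable: bp_meds
    transform: identity
    coefficient: 0.55
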