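# Omani diabetes risk model: age, sex, BMI, waist circumference, family
# history, antihypertensive treatment.  placeholder_coefficients:
# replace with the published values before substantive validation.
name: omani
intercept: -7.2
link: logistic
placeholder_coefficients: true
terms:
  - variable: age
    transform: identity
    coefficient: 0.04
  - variable: sex          # 1 = female
    transform: {indicator: 1}
    coefficient: -0.20
  - variable: bmi
    transform: identity
    coefficient: 0.06
  - variable: waist
    transform: identity
    coefficient: 0.02
  - variable: fh_mother
    transform: identity
    coefficient: 0.40
  - variable: fh_sister
    transform: identity
    coefficient: 0.30
  - variable: bp_meds
    transform: identity
    coefficient: 0.50
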