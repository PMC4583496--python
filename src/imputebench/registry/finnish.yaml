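# Simplified Finnish diabetes risk score: banded age, BMI and waist
# circumference, antihypertensive medication, family history; score
# converted to a logistic linear predictor.  placeholder_coefficients:
# replace with the published values before substantive validation.
name: finnish
intercept: -5.5
link: logistic
placeholder_coefficients: true
terms:
  - variable: age
    transform:
      band:
        breaks: [45.0, 55.0]
        scores: [0, 2, 3]
    coefficient: 0.30
  - variable: bmi
    transform:
      band:
        breaks: [25.0, 30.0]
        scores: [0, 1, 3]
    coefficient: 0.30
  - variable: waist
    transform:
      band:
        breaks: [88.0, 100.0]
        scores: [0, 3, 4]
    coefficient: 0.25
  - variable: bp_meds
    transform: identity
    coefficient: 0.60
  - variable: fh_mother
    transform: identity
    coefficient: 0.45
  - variable: fh_father
    transform: identity
    coefficient: 0.45
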