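# Cambridge diabetes risk model: age, sex, BMI, steroid use,
# antihypertensive medication, parental family history, smoking.
#
# placeholder_coefficients: the numeric values below are plausible-scale
# placeholders so the engine runs end to end; replace them with the
# originally published coefficients before any substantive validation.
name: cambridge
intercept: -6.0
link: logistic
placeholder_coefficients: true
terms:
  - variable: age
    transform: identity
    coefficient: 0.05
  - variable: sex          # 1 = female; men carry higher risk
    transform: {indicator: 1}
    coefficient: -0.88
  - variable: bmi
    transform:
      band:
        breaks: [25.0, 27.5, 30.0]
        scores: [0, 1, 2, 3]
    coefficient: 0.35
  - variable: corticosteroids
    transform: identity
    coefficient: 0.55
  - variable: bp_meds
    transform: identity
    coefficient: 0.68
  - variable: fh_mother
    transform: identity
    coefficient: 0.30
  - variable: fh_father
    transform: identity
    coefficient: 0.30
  - variable: smoking
    transform: {indicator: current}
    coefficient: 0.25
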