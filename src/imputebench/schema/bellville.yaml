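# Default cohort schema: 14 analysis variables plus the
# previously-diagnosed-diabetes exclusion flag.
outcome: diabetes
variables:
  - name: diabetes
    kind: binary
    labels: {1: undiagnosed diabetes, 0: no diabetes}
  - name: age
    kind: continuous
    units: years
  - name: sex
    kind: binary
    labels: {1: female, 0: male}
  - name: bmi
    kind: continuous
    units: kg/m2
  - name: waist
    kind: continuous
    units: cm
  - name: sbp
    kind: continuous
    units: mmHg
  - name: dbp
    kind: continuous
    units: mmHg
  - name: fh_mother
    kind: binary
  - name: fh_father
    kind: binary
  - name: fh_sister
    kind: binary
  - name: fh_brother
    kind: binary
  - name: corticosteroids
    kind: binary
  - name: bp_meds
    kind: binary
  - name: smoking
    kind: categorical
    categories: [current, past, "no"]
  - name: prior_diabetes
    kind: binary
    labels: {1: previously diagnosed, 0: not previously diagnosed}
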