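# Demo rule base: the two formalized STOPP/START rules (D2, D6) plus eight
# illustrative rules (X1..X8) authored for this package.  The X rules are
# NON-NORMATIVE — they are not STOPP/START content, only plausible motifs
# chosen to exercise every display-rule generator (p, a1/a2, u1/u2, drug-only
# unions, multiple unions, drug-only premises).
conditions:
  - id: constipation
    kind: clinical
    label: History of constipation
    category: digestive system
    codes: [K59.0]
  - id: diverticulosis
    kind: clinical
    label: Diverticulosis
    category: digestive system
    codes: [K57.9]
  - id: parkinsonism
    kind: clinical
    label: Parkinsonism
    category: neurology
    codes: [G20]
  - id: lewy_body
    kind: clinical
    label: Lewy body disease
    category: neurology
    codes: [G31.8]
  - id: ankle_edema
    kind: clinical
    label: Ankle edema
    category: cardiology
    codes: [R60.0]
  - id: heart_failure
    kind: clinical
    label: Heart failure
    category: cardiology
    codes: [I50, I50.1, I50.9]
    default_code: 0
  - id: diabetes
    kind: clinical
    label: Diabetes mellitus
    category: endocrinology
    codes: [E14, E10, E11]
    default_code: 0
  - id: proteinuria
    kind: clinical
    label: Proteinuria
    category: urogenital
    codes: [R80]
  - id: hypertension
    kind: clinical
    label: Hypertension
    category: cardiology
    codes: [I10]
  - id: falls
    kind: clinical
    label: History of falls
    category: general
    codes: [R29.6]
  - id: osteoporosis
    kind: clinical
    label: Osteoporosis
    category: rheumatology
    codes: [M81]
  - id: depression
    kind: clinical
    label: Depression
    category: psychiatry
    codes: [F32]
  - id: dementia
    kind: clinical
    label: Dementia
    category: neurology
    codes: [F03]
  - id: fibre
    kind: nonclinical
    label: Fibre supplements (bran, ispaghula, methylcellulose, sterculia)
    codes: [A06AC]
  - id: antipsychotic
    kind: nonclinical
    label: Antipsychotics (other than quetiapine or clozapine)
    codes: [N05A]
  - id: loop_diuretic
    kind: nonclinical
    label: Loop diuretic
    codes: [C03C]
  - id: ace_inhibitor
    kind: nonclinical
    label: ACE inhibitor
    codes: [C09A]
  - id: benzodiazepine
    kind: nonclinical
    label: Benzodiazepine
    codes: [N05BA]
  - id: ssri
    kind: nonclinical
    label: SSRI antidepressant
    codes: [N06AB]
  - id: calcium_supplement
    kind: nonclinical
    label: Calcium supplement
    codes: [A12A]
  - id: vitamin_d
    kind: nonclinical
    label: Vitamin D supplement
    codes: [A11CC]
  - id: egfr_low
    kind: nonclinical
    label: Low estimated GFR (lab)
    codes: [62238-1]
rules:
  - id: D2
    present_clinical: [constipation, diverticulosis]
    absent_nonclinical: [fibre]
    action: start(fibre)
  - id: D6
    present_nonclinical: [antipsychotic]
    unions:
      - clinical: [parkinsonism, lewy_body]
    action: stop(antipsychotic)
  # ---- illustrative, non-normative rules below ----
  - id: X1   # present + absent clinical: ask for edema first, heart failure last
    present_clinical: [ankle_edema]
    absent_clinical: [heart_failure]
    present_nonclinical: [loop_diuretic]
    action: review(loop_diuretic)
  - id: X2   # present chain gated by an absent drug
    present_clinical: [diabetes, proteinuria]
    absent_nonclinical: [ace_inhibitor]
    action: start(ace_inhibitor)
  - id: X3   # STOPP-style drug gate
    present_clinical: [falls]
    present_nonclinical: [benzodiazepine]
    action: stop(benzodiazepine)
  - id: X4   # drug-only union (vacuously retained in compiled premises)
    present_clinical: [osteoporosis]
    unions:
      - nonclinical: [calcium_supplement, vitamin_d]
    action: review(bone_protection)
  - id: X5   # two unions, one clinical and one drug-only
    unions:
      - clinical: [depression, dementia]
      - nonclinical: [ssri, benzodiazepine]
    action: review(psychotropics)
  - id: X6   # absent-only clinical premise
    present_nonclinical: [calcium_supplement]
    absent_clinical: [osteoporosis]
    action: review(calcium_supplement)
  - id: X7   # pure clinical chain
    present_clinical: [hypertension, heart_failure]
    absent_nonclinical: [ace_inhibitor]
    action: start(ace_inhibitor)
  - id: X8   # no clinical condition: generates no display rules
    present_nonclinical: [loop_diuretic, ace_inhibitor]
    absent_nonclinical: [egfr_low]
    action: monitor(renal_function)
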