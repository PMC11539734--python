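# The two worked STOPP/START v2 rules, exactly as formalized:
#   START D2: start fibre supplements for diverticulosis with a history of
#             constipation  (constipation ∧ diverticulosis ∧ ¬fibre)
#   STOPP D6: stop antipsychotics in those with parkinsonism or Lewy body
#             disease  (antipsychotic ∧ (parkinsonism ∨ lewy_body))
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
  - id: fibre
    kind: nonclinical
    label: Fibre supplements (bran, ispaghula, methylcellulose, sterculia)
    codes: [A06AC]
  - id: antipsychotic
    kind: nonclinical
    label: Antipsychotics (other than quetiapine or clozapine)
    codes: [N05A]
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
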