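# Round-2 default scenario space: iron deficiency in IBD.
# NAID: 7 x 2 x 2 = 28 scenarios x 5 treatments = 140 indications.
# IDA:  7 x 3 x 2 x 2 x 2 = 168 scenarios x 6 treatments = 1008 indications.
# Totals: 196 scenarios, 1148 indications.
version: round2-default
populations:
  NAID:
    variables:
      - name: prev_treatment
        label: Previous treatment of iron deficiency
        levels:
          - none
          - oral_success
          - oral_failure
          - lowdose_iv_success
          - lowdose_iv_failure
          - highdose_iv_success
          - highdose_iv_failure
      - name: conditions
        label: Conditions associated with additional iron need
        levels: [absent, present]
      - name: activity
        label: IBD activity status
        levels: [inactive, active]
    treatments:
      - {name: none, label: "None"}
      - {name: ibd_medication, label: Adjusting IBD medication only}
      - {name: oral_iron, label: Oral iron}
      - {name: lowdose_iv, label: Low-dose IV iron}
      - {name: highdose_iv, label: High-dose IV iron}
  IDA:
    variables:
      - name: prev_treatment
        label: Previous treatment of iron deficiency
        levels:
          - none
          - oral_success
          - oral_failure
          - lowdose_iv_success
          - lowdose_iv_failure
          - highdose_iv_success
          - highdose_iv_failure
      - name: hb_band
        label: Haemoglobin level (g/dL)
        levels: [hb_lt8, hb_8_to_lt10, hb_10_to_lt12]
      - name: symptoms
        label: Physical symptoms of iron depletion
        levels: [absent, present]
      - name: conditions
        label: Conditions associated with additional iron need
        levels: [absent, present]
      - name: activity
        label: IBD activity status
        levels: [inactive, active]
    treatments:
      - {name: none, label: "None"}
      - {name: oral_iron, label: Oral iron}
      - {name: lowdose_iv, label: Low-dose IV iron}
      - {name: highdose_iv, label: High-dose IV iron}
      - {name: iv_esa, label: IV iron + ESA}
      - {name: transfusion, label: Blood transfusion}
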