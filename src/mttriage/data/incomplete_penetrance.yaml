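# Variants curated as incompletely penetrant at near homoplasmy.
# Editable: the triage tiers stratify high-HL catalog hits on this list.
incomplete_penetrance:
  - {position: 1555, ref: A, alt: G}    # MT-RNR1, aminoglycoside ototoxicity susceptibility
  - {position: 3243, ref: A, alt: G}    # MT-TL1, asymptomatic high-HL blood carriers reported
  - {position: 3460, ref: G, alt: A}    # MT-ND1, LHON
  - {position: 11778, ref: G, alt: A}   # MT-ND4, LHON
  - {position: 14484, ref: T, alt: C}   # MT-ND6, LHON
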