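# Key phrases for per-post patient/caregiver labeling.  "MDS" in any phrase
# also matches the spelled-out "myelodysplastic syndrome(s)".  Caregiver
# phrases are kin-noun patterns; {kin} expands to each kin noun.
patient:
  - "I have MDS"
  - "I was diagnosed with MDS"
  - "I am living with MDS"
  - "I suffer from MDS"
caregiver_patterns:
  - "my {kin} was diagnosed with MDS"
  - "my {kin} has MDS"
  - "my {kin} is living with MDS"
  - "my {kin} suffers from MDS"
  - "I care for my {kin}"
  - "caring for my {kin}"
kin_nouns: [husband, wife, mother, father, mom, dad, son, daughter, brother, sister, partner, grandmother, grandfather]
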