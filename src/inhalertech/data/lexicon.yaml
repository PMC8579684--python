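# Keyword lexicon and combination rules for inhaler-technique documentation.
# A trailing asterisk on a keyword means prefix matching (match any
# characters after the stem).  Rule (a) requires a co-occurrence of groups
# 1 and 2; rule (b) of groups 1, 3 and 4.
groups:
  "1":
    - "observ*"
    - "reassess*"
    - "review*"
    - "demonstrat*"
    - "check*"
    - "educat*"
    - "teach*"
    - "taught"
    - "explain*"
    - "reinforce*"
    - "discuss*"
    - "instruction"
    - "constraints"
    - "how to use"
  "2":
    - "inhaler"
    - "MDI"
    - "neb"
    - "nebulizer"
    - "optichamber"
    - "spacer"
  "3":
    - "techniques"
    - "administrations"
    - "dosing"
    - "guidance"
  "4":
    - "asthma/rescue/daily/preventive/control medication"
    - "ICS"
    - "list of maintenance and rescue medications"
rules:
  a: [1, 2]
  b: [1, 3, 4]
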