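# Demo code-set registry for the diverticular-disease severity phenotyper.
# One key per named set; entries are "VOCAB:pattern" strings where a pattern
# ending in "*" is a prefix match (dot- and case-insensitive).
#
# The K57 family is split by the "with diverticulitis" designation:
# diverticulosis keeps the "without diverticulitis" codes, diverticulitis
# takes the rest. ICD-9 analog: 562.10/562.12 vs 562.11/562.13.
# CPT lists are illustrative; review against your institution's extracts.

diverticulosis_dx:
  - "ICD10CM:K57.10"
  - "ICD10CM:K57.11"
  - "ICD10CM:K57.30"
  - "ICD10CM:K57.31"
  - "ICD10CM:K57.50"
  - "ICD10CM:K57.51"
  - "ICD10CM:K57.90"
  - "ICD10CM:K57.91"
  - "ICD9CM:562.10"
  - "ICD9CM:562.12"

diverticulitis_dx:
  - "ICD10CM:K57.00"
  - "ICD10CM:K57.01"
  - "ICD10CM:K57.12"
  - "ICD10CM:K57.13"
  - "ICD10CM:K57.20"
  - "ICD10CM:K57.21"
  - "ICD10CM:K57.32"
  - "ICD10CM:K57.33"
  - "ICD10CM:K57.40"
  - "ICD10CM:K57.41"
  - "ICD10CM:K57.52"
  - "ICD10CM:K57.53"
  - "ICD10CM:K57.80"
  - "ICD10CM:K57.81"
  - "ICD10CM:K57.92"
  - "ICD10CM:K57.93"
  - "ICD9CM:562.11"
  - "ICD9CM:562.13"

diverticular_any_dx:
  - "ICD10CM:K57*"
  - "ICD9CM:562.1*"

abdominal_ct:
  - "CPT:74150"
  - "CPT:74160"
  - "CPT:74170"
  - "CPT:74176"
  - "CPT:74177"
  - "CPT:74178"

lower_gi_endoscopy:
  - "CPT:45378"
  - "CPT:45380"
  - "CPT:45384"
  - "CPT:45385"
  - "CPT:45330"
  - "CPT:45331"
  - "CPT:44388"

colectomy:
  - "CPT:44140"
  - "CPT:44141"
  - "CPT:44143"
  - "CPT:44145"
  - "CPT:44146"
  - "CPT:44160"
  - "CPT:44204"
  - "CPT:44205"
  - "CPT:44207"
  - "CPT:44208"

percutaneous_drain:
  - "CPT:49406"
  - "CPT:49020"
  - "CPT:49021"

fistula_repair:
  - "CPT:44650"
  - "CPT:44660"
  - "CPT:44661"
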