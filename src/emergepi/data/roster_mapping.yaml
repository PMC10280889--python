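# Default duty-roster mapping: which on-call arm (surgical or medical) covers
# each ICD-10 capital-letter chapter group. The split mirrors the patient
# distribution routines of a typical small/medium hospital with one surgical
# and one medical on-call team; every hospital's routines differ, so edit
# freely. Category-level entries (bottom) override chapter-level ones.
chapters:
  "A/B": medical   # infectious and parasitic diseases
  C: medical       # neoplasms (commonly split per category; override below)
  D: medical       # blood, blood-forming organs, in-situ/benign neoplasms
  E: medical       # endocrine, nutritional, metabolic
  F: medical       # mental and behavioural disorders
  G: medical       # nervous system
  H: surgical      # eye and ear (ophthalmology / ENT on-call)
  I: medical       # circulatory system
  J: medical       # respiratory system
  K: surgical      # digestive system (acute abdomen)
  L: medical       # skin and subcutaneous tissue
  M: surgical      # musculoskeletal (orthopaedics)
  N: medical       # genitourinary system
  O: surgical      # pregnancy, childbirth, puerperium
  P: medical       # perinatal conditions
  Q: surgical      # congenital malformations
  R: medical       # symptoms, signs, abnormal findings
  S: surgical      # injuries by body region
  T: surgical      # injuries, poisoning, external-cause consequences
  U: medical       # provisional/emergency-use codes
  V: surgical      # transport accidents
  W: surgical      # other external causes of injury
  X: surgical      # external causes (exposure, assault)
  Y: surgical      # external causes (complications of care, sequelae)
# Category-level overrides, e.g.:
#   K52: medical   # non-infective gastroenteritis handled by the medical team
categories: {}
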