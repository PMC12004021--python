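# Regex keyword table for Finnish free-text phenotyping (case-insensitive).
#
# Alcohol patterns are the published search stems; the smoking stems are
# artifact-chosen defaults (the study's full keyword list is supplementary
# and not redistributed).  Findings of kind "negation" suppress any
# positive finding whose span overlaps theirs, then convert to the
# category/status they carry.  Patterns are applied per text event; every
# match yields one finding with its matched span.
patterns:
  - kind: alcohol_category
    negation: true
    category: none
    regex: 'ei\s*\w*\s*alkohol'
  - kind: alcohol_category
    category: heavy
    regex: 'runsa\w*\s*alkohol\w*'
  - kind: alcohol_category
    category: heavy
    regex: 'vieroitus|vierotus|päihtymys|putki|katkaisu'
  - kind: alcohol_category
    category: moderate
    regex: 'käyt(?:ä|tä)\w*\s+alkohol\w*'
  - kind: smoking_negative
    negation: true
    regex: 'ei\s+(?:ole\s+)?(?:enää\s+)?tupako\w*|tupakoimaton|savuton'
  - kind: smoking_positive
    regex: 'tupako\w*|poltta\w*\s+(?:savuk|tupak)\w*'
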