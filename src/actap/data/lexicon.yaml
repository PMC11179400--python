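# Complication search lexicon and negation grammar.
# complication_terms is the surgeon-interview-derived phrase list used for
# the free-text complication search; the negation grammar follows the
# NegEx convention (cue within a token window, scope broken by contrast
# conjunctions and sentence punctuation).
complication_terms:
  - lens touch
  - iris touch
  - cornea touch
  - bleeding
  - hemorrhage
  - hyphema
  - tear
  - leak
  - shallow
  - movement
  - suprachoroidal
  - endophthalmitis
negation_cues_pre:
  - "no"
  - "not"
  - without
  - denies
  - denied
  - negative for
  - free of
  - absent
  - "(-)"
negation_cues_post:
  - was not seen
  - were not seen
  - not noted
  - ruled out
scope_terminators:
  - but
  - however
  - although
  - though
  - yet
  - "."
  - ";"
  - ":"
window_tokens: 5
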