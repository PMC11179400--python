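# Anesthesia-section search tokens and the "general"-misuse grammar.
# The misuse pattern operationalizes imprecise charting such as
# "transient general anesthesia" written for local anesthesia with
# intravenous sedation: "general" shortly after "transient", or
# co-occurring with a sedation marker plus at least one local term.
terms:
  - topical
  - intracameral
  - subtenon
  - peribulbar
  - retrobulbar
  - lidocaine
  - general
misuse_transient_window: 3
misuse_sedation_markers:
  - intravenous sedation
  - iv sedation
  - monitored anesthesia care
  - mac
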