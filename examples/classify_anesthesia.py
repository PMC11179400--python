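"""Anesthesia-type classification with no-hit and "general"-misuse handling.

The classifier only trusts the anesthesia section of the operative
report. Three situations need a human: sections with no informative term
("monitored anesthesia care"), adjunct-only sections, and the imprecise
"transient general anesthesia" phrasing used when the patient actually
had local anesthesia with intravenous sedation.
"""

from actap import classify

sections = [
    "topical anesthesia with intracameral lidocaine",
    "retrobulbar block with lidocaine and bupivacaine",
    "general anesthesia with endotracheal intubation",
    "transient general anesthesia with intravenous sedation and topical drops",
    "monitored anesthesia care",
]

for text in sections:
    call = classify(text, case_id="demo")
    flags = []
    if call.akinesia:
        flags.append("akinesia")
    if call.needs_review:
        flags.append(f"review:{call.review_reason}")
    print(f"{call.auto_label:10s} [{', '.join(flags) or 'clean'}]  <- {text!r}")

# The "transient general" case auto-resolves to topical but is queued for
# review; the no-hit case abstains (unknown) rather than guessing.
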