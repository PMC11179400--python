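"""Negation-aware complication flagging on a single operative report.

Shows why plain substring search fails on clinical text: most
complication terms appear in *negated* form ("no lens touch"). Mentions
within a negation cue's scope are kept as evidence but never raise a
flag; the affirmative Descemet tear does.
"""

from actap import default_lexicon, find_mentions, normalize

report = (
    "There was no lens touch and no iris touch. No bleeding, no hyphema. "
    "On aspiration a small Descemet membrane tear was noted adjacent to "
    "the paracentesis. The wound was watertight without leak."
)

lexicon = default_lexicon()
for m in find_mentions(normalize(report), lexicon):
    status = "negated " if m.negated else "FLAGGED "
    print(f"{status} {m.term:12s} | {m.excerpt}")

# Only the tear is flagged: one non-negated mention is enough, and the
# four negated mentions are retained purely as the audit evidence trail.
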