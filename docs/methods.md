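# Methods

## The surveillance problem

A surgical biobank manifest lists anterior-chamber (AH) liquid-biopsy cases
with patient identifiers and procedure dates; the EHR holds each case's
operative report (with an anesthesia section) and dated clinical notes. The
pipeline answers three questions per case: (1) did the biopsy cause an
intraoperative complication, (2) what anesthesia type was used (and hence
whether the eye was akinetic), and (3) did endophthalmitis occur *after* the
biopsy — and then aggregates rates with exact intervals, follow-up retention
and a validation audit. The method is deliberately rule-based free-text
search, not statistical NLP: every flag must be traceable to a quoted text
span a reviewer can check.

## Negation-aware flagging

Text is normalized (lowercase, Unicode quotes/dashes folded to ASCII,
whitespace collapsed; all spans refer to normalized text, 0-based half-open).
Phrases match at word boundaries where a word character is `[a-z0-9']`,
with longest-phrase-first claiming so an extended lexicon containing both
"lens touch" and "touch" counts once. There is no stemming: "tears" and
"shallowing" do not match "tear"/"shallow" unless the `match_inflections`
toggle is set, because the term list is exact by construction.

A mention is negated when a pre-cue (default: *no, not, without, denies,
denied, negative for, free of, absent, (-)*) ends within `window_tokens`
(default 5) tokens before the phrase, or a post-cue (*was not seen, were not
seen, not noted, ruled out*) starts within the window after it, with no scope
terminator (*but, however, although, though, yet*, `.`, `;`, `:`) between cue
and phrase. These defaults follow the NegEx convention and are fully
configurable in `data/lexicon.yaml`. A case's flag for a term is true iff at
least one non-negated mention exists in the operative report body or any
clinical note; adding documents can therefore flip a flag only false→true.
The matcher is property-tested against a brute-force token-scan oracle on an
enumerated cue × filler × term grammar (~1250 strings, including
terminator-bearing fillers and out-of-window gaps).

## Anesthesia classification

Only the anesthesia *section* is searched (terms: *topical, intracameral,
subtenon, peribulbar, retrobulbar, lidocaine, general*; negation off — the
signal of interest is term absence). Mapping rules: block terms outrank
topical (retrobulbar > peribulbar > subtenon > topical), because the deepest
anesthesia determines akinesia; *intracameral* and *lidocaine* are adjuncts,
and alone yield `unknown` + review (`conflicting_terms`). No term at all is a
`no_hit`: the classifier abstains rather than mining the report body, since
recovering the type from elsewhere in the report is defined as a reviewer
action. A `general` match stays `general` unless the misuse pattern fires —
"general" within 3 tokens after "transient", or co-occurring with a sedation
marker (*intravenous sedation, iv sedation, monitored anesthesia care, mac*)
plus at least one local term — in which case the case is labelled by its
local terms and queued for review (`general_ambiguous`). Akinesia ⇔ final
label ∈ {retrobulbar, general}.

The cohort summary applies review resolutions (in synthetic runs, the planted
truth stands in for the reviewer) only to needs-review/no-hit cases and
reports auto-accuracy under both readings of abstention: counting no-hit
cases as errors, and excluding them.

## Record linkage

Exact match requires agreement on MRN, normalized name (casefold, punctuation
stripped, compared as (surname, given-initial)) and DOB, plus an operative
report on the manifest's procedure date. Otherwise a candidate must agree on
≥2 of the 3 identifiers, hold a same-date report, and have the discrepant
field explainable: MRN equal as integer with length difference ≤2 (dropped
leading zeros), DOB with transposed month/day or a single edited field, or
name within Levenshtein distance 2. This is the weakest rule that uniquely
resolves the three entry-error types the generator plants, and it is
deliberately conservative: two qualifying candidates, or an unexplainable
field, stay `unresolved` (strict pipeline mode aborts listing the cases;
lenient mode excludes and logs them). No probabilistic or phonetic matching
is attempted.

## Temporal adjudication and follow-up

A case is `postoperative` endophthalmitis iff a non-negated mention sits in a
document dated strictly after the procedure date; same-day mentions
(e.g. the surgical indication in the operative report) are peri-operative and
classify as pre-existing. Undated documents are an error, not a default.

Follow-up offsets are clinical-note date minus procedure date (notes on/after
the procedure). "Followed up for W" is read as last-visit offset ≥ W with
1 week = 7 d, 1 month = 30 d, 3 months = 90 d (documented constants); day-1
retention is a visit at offset exactly 1. Because the any-visit-in-window
reading is equally defensible, both are computed and serialized; the
last-visit reading is the default.

## Safety report and audit

Rates use the Clopper–Pearson interval via beta quantiles (α = 0.05 default);
the implementation is cross-checked in tests against statsmodels'
independent beta-method interval to 1e-6 and against the 0-event closed form
1 − (α/2)^(1/n). Display rounding: 2 decimal places below 1%, 1 decimal
otherwise. Flags are grouped into display rows (tear → "Descemet membrane
tear", etc.); generic *bleeding/hemorrhage* flags fold into the Hyphema row
unless *suprachoroidal* is also flagged for the case, so row counts sum to
the total whenever each case has a single complication category.

The audit samples `round(fraction·n)` cases uniformly without replacement
(seeded PCG64) and scores the *adjudicated* flag table — endophthalmitis =
postoperative only — against the reviewer table, because a pre-existing
infection history is not a complication and would otherwise be a spurious
disagreement. Accuracy is exactly 1 − disagreements/audit_n. Sampling is
simple (unstratified) random.

## The synthetic cohort

The default profile plants, as exact assigned counts (never sampled
proportions): 1418 cases on 1154 patients (264 patients contribute a second
case — the true repeat structure of the reference cohort is not published, so
one-repeat-max is an assumption) by 17 surgeons, each surgeon using a single
technique with a 65.7% needle split; the full 38-row diagnosis mix; anesthesia
1021/125/61/147/64; 50 no-hit sections (empty or "monitored anesthesia
care"); 104 sections containing "general", of which 40 are misuse over local
anesthesia (planted as topical truth); 14 pre-existing endophthalmitis
histories, including all 6 endophthalmitis-indication cases, each planted as
a clinical note dated 1–5 years before surgery; exactly one Descemet tear
with affirmative language; and 14 manifest entry errors (5 dropped-leading-
zero MRNs, 5 wrong DOBs, 4 misspelled surnames — the reference does not
break down the 14, so an even split is assumed). Follow-up last-visit offsets
are planted to the retention fractions 1408/1418, 1377/1418, 1256/1418,
978/1418, with the ≥90-day block shaped so the cohort median is 223 days and
the maximum 2003; visit schedules are {1, 7, 30, 90 (those < last), last}.
Because all counts are planted, the headline results are seed-independent;
seeds only vary names, dates and template choices, and identical profiles
yield byte-identical serialized corpora.

Template soundness is enforced by a generator self-test: flagging a generated
corpus must recover the planted truth exactly — every negative-findings
variant negates every lexicon term within the cue window, and the affirmative
tear sentence keeps every cue out of scope.

Deliberate simplifications, hence what passing tests do *not* show about real
data: note text is template-composed (no misspellings, no surgeon idiolect,
no copy-forward); diagnosis labels never appear in note bodies (several
contain lexicon terms, e.g. "vitreous hemorrhage"); each clinical note is
attached to the surgery episode it follows rather than to the patient, so
patient-level note sharing between a patient's two cases is not emulated; and
benign uses of ambiguous terms ("tear film", "leak-free wound") are absent by
default. The `adversarial` flag injects such benign phrases into ~5% of
non-complicated reports to quantify the false-positive cost of that language;
no accuracy claim is made for that mode.

## Problem sizes and numerical choices

The packaged cohort (1418 cases, ~7900 documents) runs end-to-end in a few
seconds; property sweeps use 100 random profiles of 20–80 cases. All
randomness flows through a single numpy PCG64 generator seeded from the
profile (or the audit seed); derived seeds stay below 2^31. Ties and
degenerate inputs: empty profiles generate empty corpora; an empty manifest
is a pipeline error ("no cases"); a report for n = 0 cases is an error; CI
endpoints at k = 0 and k = n use the conventional 0 and 1.
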