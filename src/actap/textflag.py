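"""Negation-aware free-text complication search.

Operative reports and clinical notes are searched for an ordered lexicon
of complication phrases ("lens touch", "hyphema", "tear", ...). Each
occurrence becomes a :class:`Mention` with a character span and an
evidence excerpt, and is labelled negated when a negation cue ("no",
"without", "ruled out", ...) occurs within a small token window before
(or after, for post-cues) the phrase with no scope terminator — a
contrast conjunction or sentence punctuation — in between. A case's
:class:`FlagSet` raises a term's binary flag iff at least one
non-negated mention of the term exists anywhere in the case's searched
documents; negated mentions are retained as evidence but never flag.

Matching is at word boundaries on normalized text (lowercased, Unicode
quotes/dashes folded to ASCII, whitespace collapsed), with no stemming:
"tears" does not match "tear" unless the inflection toggle is enabled.
Longer phrases are matched first so a user-extended lexicon containing
both "lens touch" and "touch" never double-counts.
"""

from __future__ import annotations

import re
from bisect import bisect_right
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, List, Mapping, Optional, Sequence

import yaml

__all__ = [
    "TermLexicon",
    "Mention",
    "FlagSet",
    "MissingOperativeReportError",
    "normalize",
    "tokenize",
    "find_mentions",
    "match_terms",
    "flag_case",
    "default_lexicon",
]

# Unicode quote/dash folding applied before matching.
_CHAR_MAP = str.maketrans(
    {
        "“": '"', "”": '"', "„": '"', "‟": '"',
        "‘": "'", "’": "'", "‚": "'", "‛": "'", "′": "'",
        "–": "-", "—": "-", "―": "-", "−": "-", "‐": "-",
        "‑": "-", " ": " ",
    }
)

_TOKEN_RE = re.compile(r"[a-z0-9']+|[^\sa-z0-9']")


def normalize(text: str) -> str:
    """Lowercase, fold Unicode quotes/dashes to ASCII, collapse whitespace.

    Mention spans always refer to offsets in the normalized text.
    """
    return " ".join(text.lower().translate(_CHAR_MAP).split())


@dataclass(frozen=True)
class Token:
    text: str
    start: int
    end: int


def tokenize(text: str) -> List[Token]:
    """Split normalized text into word and punctuation tokens with spans."""
    return [Token(m.group(0), m.start(), m.end()) for m in _TOKEN_RE.finditer(text)]


class MissingOperativeReportError(KeyError):
    """A case was flagged without an operative report among its documents."""


@dataclass
class TermLexicon:
    """Search phrases plus the negation grammar.

    ``window_tokens`` is the maximum token distance between a cue and the
    phrase; a scope terminator between them blocks negation.
    """

    complication_terms: Sequence[str]
    negation_cues_pre: Sequence[str] = (
        "no", "not", "without", "denies", "denied", "negative for",
        "free of", "absent", "(-)",
    )
    negation_cues_post: Sequence[str] = (
        "was not seen", "were not seen", "not noted", "ruled out",
    )
    scope_terminators: Sequence[str] = (
        "but", "however", "although", "though", "yet", ".", ";", ":",
    )
    window_tokens: int = 5
    match_inflections: bool = False

    def __post_init__(self) -> None:
        terms = list(self.complication_terms)
        if not terms:
            raise ValueError("complication_terms must be non-empty")
        if any(t != t.lower() or not t.strip() for t in terms):
            raise ValueError("complication_terms must be lowercase and non-blank")
        if len(set(terms)) != len(terms):
            raise ValueError("complication_terms must not contain duplicates")


#: The packaged complication term list.
DEFAULT_COMPLICATION_TERMS = (
    "lens touch", "iris touch", "cornea touch", "bleeding", "hemorrhage",
    "hyphema", "tear", "leak", "shallow", "movement", "suprachoroidal",
    "endophthalmitis",
)


def default_lexicon() -> TermLexicon:
    """Load the packaged lexicon (terms + negation grammar) from YAML."""
    raw = yaml.safe_load(
        resources.files("actap.data").joinpath("lexicon.yaml").read_text()
    )
    return TermLexicon(
        complication_terms=tuple(raw["complication_terms"]),
        negation_cues_pre=tuple(raw["negation_cues_pre"]),
        negation_cues_post=tuple(raw["negation_cues_post"]),
        scope_terminators=tuple(raw["scope_terminators"]),
        window_tokens=int(raw["window_tokens"]),
    )


@dataclass
class Mention:
    """One occurrence of a lexicon phrase, with evidence for manual review."""

    term: str
    start: int
    end: int
    negated: bool
    excerpt: str
    doc_id: Optional[str] = None


@dataclass
class FlagSet:
    """Per-case binary complication flags plus the mention evidence trail."""

    case_id: str
    flags: Mapping[str, bool]
    mentions: List[Mention] = field(default_factory=list)
    source_text_refs: List[str] = field(default_factory=list)

    def any_flagged(self, exclude: Iterable[str] = ()) -> bool:
        skip = set(exclude)
        return any(v for k, v in self.flags.items() if k not in skip)


_SENTENCE_BREAK = ".;:"


def _excerpt(text: str, start: int, end: int) -> str:
    lo = max(text.rfind(ch, 0, start) for ch in _SENTENCE_BREAK) + 1
    hits = [text.find(ch, end) for ch in _SENTENCE_BREAK]
    hits = [h for h in hits if h != -1]
    hi = min(hits) + 1 if hits else len(text)
    return text[lo:hi].strip()


def _phrase_regex(phrase: str, inflections: bool) -> re.Pattern:
    # custom word boundaries: a word char is [a-z0-9'] to match the tokenizer
    body = re.escape(phrase)
    if inflections:
        body += r"(?:s|es|ed|ing)?"
    return re.compile(r"(?<![a-z0-9'])" + body + r"(?![a-z0-9'])")


def _cue_tokens(cues: Sequence[str]) -> List[List[str]]:
    return [[t.text for t in tokenize(normalize(c))] for c in cues]


def find_mentions(text: str, lexicon: TermLexicon) -> List[Mention]:
    """All word-boundary occurrences of lexicon phrases, negation-labelled.

    ``text`` must already be normalized. Longest phrases claim their
    tokens first, so overlapping shorter phrases are suppressed.
    """
    tokens = tokenize(text)
    tok_texts = [t.text for t in tokens]
    tok_starts = [t.start for t in tokens]

    # collect candidate matches, longest (by token count, then chars) first
    candidates = []
    for term in lexicon.complication_terms:
        n_tok = len(tokenize(term))
        rx = _phrase_regex(term, lexicon.match_inflections)
        for m in rx.finditer(text):
            candidates.append((term, n_tok, m.start(), m.end()))
    candidates.sort(key=lambda c: (-c[1], -(c[3] - c[2]), c[2]))

    claimed: set = set()
    pre_cues = _cue_tokens(lexicon.negation_cues_pre)
    post_cues = _cue_tokens(lexicon.negation_cues_post)
    terminators = set(lexicon.scope_terminators)
    window = lexicon.window_tokens

    accepted = []
    for term, _n_tok, start, end in candidates:
        ti = bisect_right(tok_starts, start) - 1
        tj = bisect_right(tok_starts, end - 1) - 1
        span_tokens = range(ti, tj + 1)
        if any(i in claimed for i in span_tokens):
            continue
        claimed.update(span_tokens)
        negated = _negated_before(
            tok_texts, ti, pre_cues, terminators, window
        ) or _negated_after(tok_texts, tj, post_cues, terminators, window)
        accepted.append(
            Mention(term=term, start=start, end=end, negated=negated,
                    excerpt=_excerpt(text, start, end))
        )
    accepted.sort(key=lambda m: m.start)
    return accepted


def _negated_before(tokens, term_start, cues, terminators, window) -> bool:
    for cue in cues:
        m = len(cue)
        # cue's last token at index q; gap term_start - q must be in [1, window]
        for q in range(term_start - 1, max(term_start - window, m - 1) - 1, -1):
            if tokens[q - m + 1 : q + 1] == cue:
                if not any(t in terminators for t in tokens[q + 1 : term_start]):
                    return True
    return False


def _negated_after(tokens, term_end, cues, terminators, window) -> bool:
    n = len(tokens)
    for cue in cues:
        m = len(cue)
        for p in range(term_end + 1, min(term_end + window, n - m) + 1):
            if tokens[p : p + m] == cue:
                if not any(t in terminators for t in tokens[term_end + 1 : p]):
                    return True
    return False


def match_terms(text: str, terms: Sequence[str]) -> List[Mention]:
    """Plain word-boundary term search with negation detection disabled.

    Used by the anesthesia classifier, where "no hit" (absence of every
    term) is itself the signal and negation is irrelevant.
    """
    lex = TermLexicon(complication_terms=tuple(terms), negation_cues_pre=(),
                      negation_cues_post=())
    return find_mentions(normalize(text), lex)


def flag_case(case, docs, lexicon: Optional[TermLexicon] = None) -> FlagSet:
    """Binary complication flags for one case from all its documents.

    Searches the operative report body plus every clinical note; the
    flag for a term is true iff any non-negated mention exists. The
    endophthalmitis flag here is raw — whether a mention predates the
    biopsy is adjudicated by the temporal stage.

    Raises :class:`MissingOperativeReportError` naming the case when no
    operative report is among ``docs`` (a linkage failure upstream).
    """
    lexicon = lexicon or default_lexicon()
    if not any(d.kind == "operative_report" for d in docs):
        raise MissingOperativeReportError(
            f"case {case.case_id}: no operative report among documents"
        )
    mentions: List[Mention] = []
    refs: List[str] = []
    for doc in docs:
        refs.append(doc.doc_id)
        for m in find_mentions(normalize(doc.body), lexicon):
            m.doc_id = doc.doc_id
            mentions.append(m)
    flags = {
        term: any(m.term == term and not m.negated for m in mentions)
        for term in lexicon.complication_terms
    }
    return FlagSet(case_id=case.case_id, flags=flags, mentions=mentions,
                   source_text_refs=refs)
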