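"""Anesthesia-type classification from the operative report's anesthesia section.

The section text is term-searched (negation off — absence of every term
is itself the "no hit" signal) and mapped to a final label by a small
rule table. Block anesthesia outranks topical (deepest anesthesia
determines akinesia): retrobulbar > peribulbar > subtenon > topical;
"intracameral" and "lidocaine" are adjuncts, not standalone labels. A
"general" match is kept as general unless the misuse pattern fires —
"general" shortly after "transient", or co-occurring with a sedation
marker plus at least one local term — in which case the case is labelled
by its local terms and queued for review, mirroring imprecise "transient
general anesthesia" charting for local anesthesia with IV sedation.

No-hit and ambiguous cases are never silently guessed: they carry
``needs_review`` and a reason, and :func:`summarize` accepts a review
resolution table (in synthetic runs, planted ground truth standing in
for the manual reviewer) to assign final labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Tuple

import yaml

from .profile import AKINESIA_LABELS
from .records import Document
from .textflag import match_terms, normalize, tokenize

__all__ = [
    "AnesthesiaLexicon",
    "AnesthesiaCall",
    "AnesthesiaSummary",
    "default_anesthesia_lexicon",
    "extract_anesthesia_text",
    "classify",
    "summarize",
]

# block-before-topical precedence; first matched wins for local labels
_PRECEDENCE = ("retrobulbar", "peribulbar", "subtenon", "topical")
_ADJUNCTS = frozenset({"lidocaine", "intracameral"})


@dataclass
class AnesthesiaLexicon:
    terms: Sequence[str]
    misuse_transient_window: int = 3
    misuse_sedation_markers: Sequence[str] = (
        "intravenous sedation", "iv sedation", "monitored anesthesia care", "mac",
    )

    def __post_init__(self) -> None:
        terms = list(self.terms)
        if not terms or len(set(terms)) != len(terms):
            raise ValueError("terms must be non-empty and unique")
        if any(t != t.lower() for t in terms):
            raise ValueError("terms must be lowercase")


def default_anesthesia_lexicon() -> AnesthesiaLexicon:
    raw = yaml.safe_load(
        resources.files("actap.data").joinpath("anesthesia_lexicon.yaml").read_text()
    )
    return AnesthesiaLexicon(
        terms=tuple(raw["terms"]),
        misuse_transient_window=int(raw["misuse_transient_window"]),
        misuse_sedation_markers=tuple(raw["misuse_sedation_markers"]),
    )


@dataclass
class AnesthesiaCall:
    """Classification of one case's anesthesia section."""

    case_id: str
    matched_terms: FrozenSet[str]
    auto_label: str  # topical|peribulbar|subtenon|retrobulbar|general|unknown
    akinesia: bool
    no_hit: bool
    needs_review: bool
    review_reason: str  # none|no_hit|general_ambiguous|conflicting_terms
    final_label: Optional[str] = None


def extract_anesthesia_text(report: Document) -> Optional[str]:
    """The anesthesia section when present and non-empty, else ``None``.

    An absent section triggers the no-hit path downstream; recovering the
    type from the report body is a manual-review action, not automated.
    """
    if report.kind != "operative_report":
        raise ValueError(f"{report.doc_id}: not an operative report")
    text = report.anesthesia_text
    if text is None or not text.strip():
        return None
    return text


def _misuse_pattern(text: str, matched: FrozenSet[str],
                    lexicon: AnesthesiaLexicon) -> bool:
    tokens = [t.text for t in tokenize(normalize(text))]
    transient = [i for i, t in enumerate(tokens) if t == "transient"]
    general = [i for i, t in enumerate(tokens) if t == "general"]
    near = any(
        0 < g - t <= lexicon.misuse_transient_window
        for t in transient for g in general
    )
    if near:
        return True
    has_local = any(t in matched for t in _PRECEDENCE)
    if not has_local:
        return False
    markers = {m.term for m in match_terms(text, lexicon.misuse_sedation_markers)}
    return bool(markers)


def classify(
    call_text: Optional[str],
    body: str = "",
    lexicon: Optional[AnesthesiaLexicon] = None,
    case_id: str = "",
) -> AnesthesiaCall:
    """Rule-table classification of an anesthesia section.

    ``body`` is accepted for interface completeness; the automated path
    deliberately does not mine the report body (that is the reviewer's
    recovery action for no-hit sections).
    """
    lexicon = lexicon or default_anesthesia_lexicon()
    text = call_text or ""
    mentions = match_terms(text, lexicon.terms) if text.strip() else []
    matched = frozenset(m.term for m in mentions)

    no_hit = not matched
    needs_review, reason = False, "none"
    if no_hit:
        label = "unknown"
        needs_review, reason = True, "no_hit"
    elif "general" in matched:
        local = [t for t in _PRECEDENCE if t in matched]
        if local and _misuse_pattern(text, matched, lexicon):
            label = local[0]
            needs_review, reason = True, "general_ambiguous"
        else:
            label = "general"
    else:
        local = [t for t in _PRECEDENCE if t in matched]
        if local:
            label = local[0]
        else:  # only adjunct terms (lidocaine / intracameral)
            label = "unknown"
            needs_review, reason = True, "conflicting_terms"

    return AnesthesiaCall(
        case_id=case_id,
        matched_terms=matched,
        auto_label=label,
        akinesia=label in AKINESIA_LABELS,
        no_hit=no_hit,
        needs_review=needs_review,
        review_reason=reason,
    )


@dataclass
class AnesthesiaSummary:
    """Cohort-level anesthesia statistics after review resolution."""

    n: int
    label_counts: Dict[str, int]
    no_hit_count: int
    no_hit_fraction: float
    general_term_count: int
    general_resolved_local_count: int
    akinesia_count: int
    akinesia_fraction: float
    n_review: int
    accuracy_all: float
    accuracy_excluding_no_hit: float
    accuracy_non_review: float


def summarize(
    calls: Sequence[AnesthesiaCall],
    resolutions: Optional[Mapping[str, str]] = None,
) -> AnesthesiaSummary:
    """Final labels, ambiguity counts and auto-accuracy for a cohort.

    ``resolutions`` maps case_id to the reviewer's final label and is
    applied only to needs_review / no-hit cases. Auto-accuracy is the
    fraction of cases whose automatic label already equals the final
    label; because whether abstentions (no-hit) count as errors is a
    reporting choice, the no-hit-excluded reading is reported alongside.
    """
    resolutions = resolutions or {}
    seen = set()
    for c in calls:
        if c.case_id in seen:
            raise ValueError(f"duplicate case_id {c.case_id!r}")
        seen.add(c.case_id)

    n = len(calls)
    label_counts: Dict[str, int] = {}
    no_hit = general_terms = general_local = akinesia = 0
    n_review = correct = correct_non_nohit = correct_non_review = n_non_review = 0

    for c in calls:
        final = c.auto_label
        if (c.needs_review or c.no_hit) and c.case_id in resolutions:
            final = resolutions[c.case_id]
        c.final_label = final
        label_counts[final] = label_counts.get(final, 0) + 1
        if c.no_hit:
            no_hit += 1
        if "general" in c.matched_terms:
            general_terms += 1
            if final not in ("general", "unknown"):
                general_local += 1
        if final in AKINESIA_LABELS:
            akinesia += 1
        if c.needs_review:
            n_review += 1
        ok = c.auto_label == final
        correct += ok
        if not c.no_hit:
            correct_non_nohit += ok
        if not c.needs_review:
            n_non_review += 1
            correct_non_review += ok

    return AnesthesiaSummary(
        n=n,
        label_counts=label_counts,
        no_hit_count=no_hit,
        no_hit_fraction=no_hit / n if n else 0.0,
        general_term_count=general_terms,
        general_resolved_local_count=general_local,
        akinesia_count=akinesia,
        akinesia_fraction=akinesia / n if n else 0.0,
        n_review=n_review,
        accuracy_all=correct / n if n else 1.0,
        accuracy_excluding_no_hit=(
            correct_non_nohit / (n - no_hit) if n > no_hit else 1.0
        ),
        accuracy_non_review=(
            correct_non_review / n_non_review if n_non_review else 1.0
        ),
    )
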