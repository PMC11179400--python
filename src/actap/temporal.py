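"""Temporal adjudication of endophthalmitis mentions and follow-up arithmetic.

A raw endophthalmitis flag only says the word appears somewhere in the
patient record; whether it represents a postoperative infection depends
on dates. A case is ``postoperative`` iff at least one non-negated
mention sits in a document dated strictly after the procedure date;
mentions on or before that date (including the surgical indication in
the operative report itself) are ``preexisting_only``.

Follow-up: a case's visit offsets are clinical-note dates minus the
procedure date (notes on/after the procedure only). "Followed up for W"
is read as last-visit offset >= W days (1 week = 7, 1 month = 30,
3 months = 90); day-1 retention is a visit at offset exactly 1. The
alternative any-visit-within-window reading is computed alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from statistics import median
from typing import Dict, List, Optional, Sequence, Tuple

from .records import CaseRecord, Document
from .textflag import Mention

__all__ = [
    "DatedMention",
    "TemporalClassification",
    "FollowupSummary",
    "classify_endophthalmitis",
    "followup_summary",
]

_WINDOWS = (("week1", 7), ("month1", 30), ("month3", 90))


@dataclass(frozen=True)
class DatedMention:
    """A mention paired with its document's date (mandatory for adjudication)."""

    mention: Mention
    date: Optional[date]


@dataclass
class TemporalClassification:
    case_id: str
    n_mentions: int
    earliest_mention_date: Optional[date]
    classification: str  # none | preexisting_only | postoperative


def classify_endophthalmitis(
    case: CaseRecord, mentions: Sequence[DatedMention]
) -> TemporalClassification:
    """Classify a case's endophthalmitis mentions relative to the biopsy date.

    Only non-negated mentions of the term count. An undated document is
    an error: the date comparison is the whole point.
    """
    relevant = [
        dm for dm in mentions
        if dm.mention.term == "endophthalmitis" and not dm.mention.negated
    ]
    for dm in relevant:
        if dm.date is None:
            raise ValueError(
                f"case {case.case_id}: undated document for mention "
                f"{dm.mention.doc_id!r}"
            )
    if not relevant:
        return TemporalClassification(case.case_id, 0, None, "none")
    dates = sorted(dm.date for dm in relevant)
    post = any(d > case.procedure_date for d in dates)
    return TemporalClassification(
        case_id=case.case_id,
        n_mentions=len(relevant),
        earliest_mention_date=dates[0],
        classification="postoperative" if post else "preexisting_only",
    )


@dataclass
class FollowupSummary:
    """Retention table plus median/range of last-visit offsets."""

    n: int
    last_offset: Dict[str, int]
    day1_count: int
    retention_counts: Dict[str, int]            # last-visit >= W reading
    retention_any_visit_counts: Dict[str, int]  # any visit in [1, W] reading
    median_days: float
    min_days: int
    max_days: int

    @property
    def day1_fraction(self) -> float:
        return self.day1_count / self.n if self.n else 0.0

    def retention_fraction(self, window: str) -> float:
        return self.retention_counts[window] / self.n if self.n else 0.0


def followup_summary(
    manifest: Sequence[CaseRecord], documents: Sequence[Document]
) -> FollowupSummary:
    """Visit-date arithmetic over a cohort's clinical notes."""
    offsets_by_case: Dict[str, List[int]] = {c.case_id: [] for c in manifest}
    proc = {c.case_id: c.procedure_date for c in manifest}
    for doc in documents:
        if doc.kind != "clinical_note" or doc.case_id not in proc:
            continue
        off = (doc.date - proc[doc.case_id]).days
        if off >= 0:
            offsets_by_case[doc.case_id].append(off)

    last = {cid: max(offs, default=0) for cid, offs in offsets_by_case.items()}
    day1 = sum(1 in offs for offs in offsets_by_case.values())
    retention = {
        name: sum(v >= w for v in last.values()) for name, w in _WINDOWS
    }
    any_visit = {
        name: sum(
            any(1 <= o <= w for o in offs) for offs in offsets_by_case.values()
        )
        for name, w in _WINDOWS
    }
    values = list(last.values())
    return FollowupSummary(
        n=len(manifest),
        last_offset=last,
        day1_count=day1,
        retention_counts=retention,
        retention_any_visit_counts=any_visit,
        median_days=float(median(values)) if values else 0.0,
        min_days=min(values) if values else 0,
        max_days=max(values) if values else 0,
    )
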