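"""Biobank-manifest / EHR record linkage with entry-error resolution.

Each manifest row is matched against an EHR patient directory on
(MRN, name, date of birth) plus the presence of an operative report on
the manifest's procedure date. When all three identifiers agree the link
is exact. Otherwise a candidate must agree on at least two of the three
identifiers, hold a same-date operative report, and have its remaining
discrepant field explainable by a known entry-error rule:

* MRN differing only by dropped leading zeros (same integer value,
  length difference at most two digits);
* DOB with transposed month/day, or a single date field edited;
* name within Levenshtein edit distance two after normalization.

Two distinct patients satisfying the rule is an ambiguity and stays
unresolved — the linker never auto-picks.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from datetime import date
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

from .records import CaseRecord, Document

__all__ = [
    "LinkageResult",
    "EHRPatient",
    "build_ehr_index",
    "link_case",
    "link_all",
]

_PUNCT = str.maketrans("", "", string.punctuation)


@dataclass
class EHRPatient:
    """One patient on the EHR side, with operative-report dates."""

    mrn: str
    name: str
    dob: date
    op_report_dates: Set[date] = field(default_factory=set)


@dataclass
class LinkageResult:
    case_id: str
    status: str  # exact_match | resolved | unresolved
    discrepant_fields: Tuple[str, ...] = ()
    resolution_note: str = ""


def build_ehr_index(documents: Iterable[Document]) -> Dict[str, EHRPatient]:
    """Patient directory keyed by MRN, built from EHR documents."""
    index: Dict[str, EHRPatient] = {}
    for doc in documents:
        if not doc.patient_mrn:
            continue
        patient = index.setdefault(
            doc.patient_mrn,
            EHRPatient(mrn=doc.patient_mrn, name=doc.patient_name,
                       dob=doc.patient_dob),
        )
        if doc.kind == "operative_report":
            patient.op_report_dates.add(doc.date)
    return index


def normalize_name(name: str) -> str:
    return " ".join(name.casefold().translate(_PUNCT).split())


def _name_key(name: str) -> Tuple[str, str]:
    # compare (surname, given-initial): robust to given-name variants
    parts = normalize_name(name).split()
    if not parts:
        return ("", "")
    return (parts[-1], parts[0][:1])


def _levenshtein(a: str, b: str) -> int:
    if len(a) < len(b):
        a, b = b, a
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def _mrn_explainable(a: str, b: str) -> bool:
    if not (a.isdigit() and b.isdigit()):
        return False
    return int(a) == int(b) and abs(len(a) - len(b)) <= 2


def _dob_explainable(a: date, b: date) -> bool:
    if a == b:
        return False
    if a.year == b.year and a.month == b.day and a.day == b.month:
        return True  # transposed month/day
    diffs = (a.year != b.year) + (a.month != b.month) + (a.day != b.day)
    return diffs == 1  # single-field edit


def _name_explainable(a: str, b: str) -> bool:
    return _levenshtein(normalize_name(a), normalize_name(b)) <= 2


def link_case(
    manifest_row: CaseRecord, ehr_index: Dict[str, EHRPatient]
) -> LinkageResult:
    """Link one manifest row against the EHR patient directory."""
    row = manifest_row
    exact = ehr_index.get(row.mrn)
    if (
        exact is not None
        and _name_key(exact.name) == _name_key(row.name)
        and exact.dob == row.dob
        and row.procedure_date in exact.op_report_dates
    ):
        return LinkageResult(case_id=row.case_id, status="exact_match")

    candidates: List[Tuple[EHRPatient, Tuple[str, ...]]] = []
    for patient in ehr_index.values():
        if row.procedure_date not in patient.op_report_dates:
            continue
        agree = {
            "mrn": patient.mrn == row.mrn,
            "name": _name_key(patient.name) == _name_key(row.name),
            "dob": patient.dob == row.dob,
        }
        if sum(agree.values()) < 2:
            continue
        discrepant = tuple(f for f in ("mrn", "name", "dob") if not agree[f])
        ok = True
        for f in discrepant:
            if f == "mrn":
                ok = _mrn_explainable(row.mrn, patient.mrn)
            elif f == "dob":
                ok = _dob_explainable(row.dob, patient.dob)
            else:
                ok = _name_explainable(row.name, patient.name)
            if not ok:
                break
        if ok:
            candidates.append((patient, discrepant))

    if len(candidates) == 1:
        patient, discrepant = candidates[0]
        if not discrepant:
            # identifiers agree but the exact path failed (e.g. name-key tie)
            return LinkageResult(case_id=row.case_id, status="exact_match")
        note = "; ".join(
            f"{f}: manifest={getattr(row, f)} ehr={getattr(patient, f)}"
            for f in discrepant
        )
        return LinkageResult(
            case_id=row.case_id,
            status="resolved",
            discrepant_fields=discrepant,
            resolution_note=note,
        )
    if len(candidates) > 1:
        mrns = ", ".join(p.mrn for p, _ in candidates)
        return LinkageResult(
            case_id=row.case_id,
            status="unresolved",
            resolution_note=f"ambiguous: multiple EHR patients match ({mrns})",
        )
    return LinkageResult(
        case_id=row.case_id,
        status="unresolved",
        resolution_note="no EHR patient satisfies the resolution rule",
    )


def link_all(
    manifest: Sequence[CaseRecord], documents: Sequence[Document]
) -> List[LinkageResult]:
    index = build_ehr_index(documents)
    return [link_case(row, index) for row in manifest]
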