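"""Core record types: biobank cases, EHR documents, planted ground truth."""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from typing import Dict, FrozenSet, List, Optional, Tuple

__all__ = ["GroundTruth", "CaseRecord", "Document", "Corpus"]

CORRUPTION_KINDS = ("none", "mrn_leading_zero", "dob_wrong", "name_misspelled")


@dataclass
class GroundTruth:
    """Machine-readable planted truth for one synthetic case.

    Never consumed by the pipeline proper — only by tests, the audit
    stage (standing in for a manual reviewer) and review resolutions.
    """

    anesthesia_true: str
    anesthesia_section_present: bool
    general_misuse: bool
    complications_true: FrozenSet[str]
    has_preexisting_endophthalmitis: bool
    identifier_corruption: str = "none"
    followup_days: Tuple[int, ...] = ()


@dataclass
class CaseRecord:
    """One biobank manifest row. Identifier fields are manifest-side and may
    carry planted entry errors; the EHR documents hold the true values."""

    case_id: str
    mrn: str
    name: str
    dob: date
    procedure_date: date
    laterality: str  # OD | OS
    surgeon_id: str
    technique: str  # needle | cannula
    primary_diagnosis: str
    truth: Optional[GroundTruth] = None


@dataclass
class Document:
    """An operative report or dated clinical note on the EHR side."""

    doc_id: str
    case_id: str
    kind: str  # operative_report | clinical_note
    date: date
    body: str
    anesthesia_text: Optional[str] = None  # operative reports only
    patient_mrn: str = ""
    patient_name: str = ""
    patient_dob: Optional[date] = None


@dataclass
class Corpus:
    """A generated manifest + document corpus."""

    manifest: List[CaseRecord]
    documents: List[Document]

    def docs_by_case(self) -> Dict[str, List[Document]]:
        by_case: Dict[str, List[Document]] = {}
        for d in self.documents:
            by_case.setdefault(d.case_id, []).append(d)
        return by_case

    def truth_by_case(self) -> Dict[str, GroundTruth]:
        return {c.case_id: c.truth for c in self.manifest if c.truth is not None}
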