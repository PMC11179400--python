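"""Resolving biobank/EHR identifier mismatches from operating-room data entry.

A manifest row must agree with an EHR patient on at least two of
(MRN, name, DOB) and have a same-date operative report; the remaining
field must be explainable by a known entry-error pattern (dropped
leading MRN zero, transposed or edited DOB, one-or-two-letter name
misspelling). Anything else stays unresolved — the linker never guesses.
"""

from datetime import date

from actap.linkage import EHRPatient, link_case
from actap.records import CaseRecord

ehr = {"0123456": EHRPatient(mrn="0123456", name="ann smith",
                             dob=date(1950, 3, 7),
                             op_report_dates={date(2021, 6, 15)})}


def row(**kw):
    base = dict(case_id="C1", mrn="0123456", name="ann smith",
                dob=date(1950, 3, 7), procedure_date=date(2021, 6, 15),
                laterality="OD", surgeon_id="S01", technique="needle",
                primary_diagnosis="cataract")
    base.update(kw)
    return CaseRecord(**base)


for label, manifest_row in [
    ("all identifiers agree   ", row()),
    ("missing leading MRN zero", row(mrn="123456")),
    ("transposed DOB          ", row(dob=date(1950, 7, 3))),
    ("misspelled surname      ", row(name="ann smyth")),
    ("wrong MRN entirely      ", row(mrn="9999999")),
]:
    res = link_case(manifest_row, ehr)
    fields = ",".join(res.discrepant_fields) or "-"
    print(f"{label} -> {res.status:12s} discrepant: {fields}")
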