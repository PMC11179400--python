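"""Serialization: manifest CSV, JSON-lines documents, truth sidecar, outputs.

All dates are ISO-8601; text is UTF-8. The ground-truth sidecar is keyed
by case_id and is never read by the pipeline stages proper — only by
tests, review resolutions and the audit. Readers skip ``#`` comment
lines, which output writers use for provenance headers.
"""

from __future__ import annotations

import csv
import io as _io
import json
from dataclasses import asdict
from datetime import date
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, TextIO, Union

from .records import CaseRecord, Corpus, Document, GroundTruth

__all__ = [
    "write_manifest", "read_manifest",
    "write_documents", "read_documents",
    "write_truth", "read_truth",
    "write_corpus", "read_corpus",
    "manifest_csv_bytes", "documents_jsonl_bytes",
]

MANIFEST_FIELDS = (
    "case_id", "mrn", "name", "dob", "procedure_date", "laterality",
    "surgeon_id", "technique", "diagnosis",
)


def _open_w(path) -> TextIO:
    return open(path, "w", encoding="utf-8", newline="")


def write_manifest(manifest: Sequence[CaseRecord], path) -> None:
    with _open_w(path) as fh:
        _write_manifest_fh(manifest, fh)


def _write_manifest_fh(manifest, fh) -> None:
    writer = csv.writer(fh)
    writer.writerow(MANIFEST_FIELDS)
    for c in manifest:
        writer.writerow([
            c.case_id, c.mrn, c.name, c.dob.isoformat(),
            c.procedure_date.isoformat(), c.laterality, c.surgeon_id,
            c.technique, c.primary_diagnosis,
        ])


def read_manifest(path) -> List[CaseRecord]:
    cases = []
    with open(path, encoding="utf-8", newline="") as fh:
        rows = (r for r in fh if not r.startswith("#"))
        for rec in csv.DictReader(rows):
            cases.append(CaseRecord(
                case_id=rec["case_id"],
                mrn=rec["mrn"],
                name=rec["name"],
                dob=date.fromisoformat(rec["dob"]),
                procedure_date=date.fromisoformat(rec["procedure_date"]),
                laterality=rec["laterality"],
                surgeon_id=rec["surgeon_id"],
                technique=rec["technique"],
                primary_diagnosis=rec["diagnosis"],
            ))
    return cases


def _doc_obj(d: Document) -> dict:
    return {
        "doc_id": d.doc_id,
        "case_id": d.case_id,
        "kind": d.kind,
        "date": d.date.isoformat(),
        "anesthesia_text": d.anesthesia_text,
        "body": d.body,
        "patient_mrn": d.patient_mrn,
        "patient_name": d.patient_name,
        "patient_dob": d.patient_dob.isoformat() if d.patient_dob else None,
    }


def write_documents(documents: Sequence[Document], path) -> None:
    with _open_w(path) as fh:
        for d in documents:
            fh.write(json.dumps(_doc_obj(d)) + "\n")


def read_documents(path) -> List[Document]:
    docs = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            o = json.loads(line)
            docs.append(Document(
                doc_id=o["doc_id"],
                case_id=o["case_id"],
                kind=o["kind"],
                date=date.fromisoformat(o["date"]),
                body=o["body"],
                anesthesia_text=o.get("anesthesia_text"),
                patient_mrn=o.get("patient_mrn", ""),
                patient_name=o.get("patient_name", ""),
                patient_dob=(
                    date.fromisoformat(o["patient_dob"])
                    if o.get("patient_dob") else None
                ),
            ))
    return docs


def write_truth(manifest: Sequence[CaseRecord], path) -> None:
    with _open_w(path) as fh:
        for c in manifest:
            if c.truth is None:
                continue
            o = {"case_id": c.case_id, **asdict(c.truth)}
            o["complications_true"] = sorted(c.truth.complications_true)
            o["followup_days"] = list(c.truth.followup_days)
            fh.write(json.dumps(o) + "\n")


def read_truth(path) -> Dict[str, GroundTruth]:
    out: Dict[str, GroundTruth] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            o = json.loads(line)
            out[o["case_id"]] = GroundTruth(
                anesthesia_true=o["anesthesia_true"],
                anesthesia_section_present=o["anesthesia_section_present"],
                general_misuse=o["general_misuse"],
                complications_true=frozenset(o["complications_true"]),
                has_preexisting_endophthalmitis=o["has_preexisting_endophthalmitis"],
                identifier_corruption=o["identifier_corruption"],
                followup_days=tuple(o["followup_days"]),
            )
    return out


def write_corpus(corpus: Corpus, out_dir) -> Dict[str, Path]:
    """Serialize a corpus to <dir>/{manifest.csv,docs.jsonl,truth.jsonl}."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "manifest": out / "manifest.csv",
        "documents": out / "docs.jsonl",
        "truth": out / "truth.jsonl",
    }
    write_manifest(corpus.manifest, paths["manifest"])
    write_documents(corpus.documents, paths["documents"])
    write_truth(corpus.manifest, paths["truth"])
    return paths


def read_corpus(manifest_path, docs_path, truth_path=None) -> Corpus:
    manifest = read_manifest(manifest_path)
    documents = read_documents(docs_path)
    if truth_path is not None and Path(truth_path).exists():
        truths = read_truth(truth_path)
        for c in manifest:
            c.truth = truths.get(c.case_id)
    return Corpus(manifest=manifest, documents=documents)


def manifest_csv_bytes(manifest: Sequence[CaseRecord]) -> bytes:
    buf = _io.StringIO(newline="")
    _write_manifest_fh(manifest, buf)
    return buf.getvalue().encode("utf-8")


def documents_jsonl_bytes(documents: Sequence[Document]) -> bytes:
    return "".join(json.dumps(_doc_obj(d)) + "\n" for d in documents).encode("utf-8")
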