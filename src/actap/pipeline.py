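"""End-to-end orchestration: generate -> link -> flag -> anesthesia ->
temporal -> report -> audit, with serialized stage outputs and a
provenance-stamped run manifest.

The pipeline proper never consults planted ground truth except where the
study design itself injects a human: review resolutions for ambiguous
anesthesia calls and the reviewer table of the validation audit, where
the truth sidecar stands in for the manual reviewer.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence

import pandas as pd

from . import __version__ as _version
from .anesthesia import (AnesthesiaCall, AnesthesiaSummary, classify,
                         default_anesthesia_lexicon, extract_anesthesia_text,
                         summarize)
from .io import read_corpus, write_corpus
from .linkage import LinkageResult, link_all
from .profile import CohortProfile
from .records import Corpus
from .safety import (AuditResult, SafetyReport, complication_report,
                     flag_table, run_audit, truth_table)
from .synth import generate_corpus
from .temporal import (DatedMention, FollowupSummary, TemporalClassification,
                       classify_endophthalmitis, followup_summary)
from .textflag import FlagSet, TermLexicon, default_lexicon, flag_case

log = logging.getLogger("actap")

__all__ = ["PipelineConfig", "PipelineError", "PipelineResult", "run_pipeline",
           "flag_corpus", "temporal_stage", "anesthesia_stage"]


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Run configuration. Either ``profile`` (generate a corpus) or the
    three input paths must be provided."""

    out_dir: Path
    seed: int = 0
    profile: Optional[CohortProfile] = None
    manifest_path: Optional[Path] = None
    docs_path: Optional[Path] = None
    truth_path: Optional[Path] = None
    lexicon: Optional[TermLexicon] = None
    adversarial: bool = False
    strict_linkage: bool = True
    audit_fraction: float = 500 / 1418
    write_outputs: bool = True

    def digest(self) -> str:
        payload = {
            "seed": self.seed,
            "profile": None if self.profile is None else vars(self.profile).copy(),
            "manifest_path": str(self.manifest_path),
            "docs_path": str(self.docs_path),
            "adversarial": self.adversarial,
            "strict_linkage": self.strict_linkage,
            "audit_fraction": self.audit_fraction,
        }
        if payload["profile"] is not None:
            payload["profile"]["diagnosis_mix"] = list(
                map(list, payload["profile"]["diagnosis_mix"])
            )
            payload["profile"]["anesthesia_mix"] = dict(
                payload["profile"]["anesthesia_mix"]
            )
            payload["profile"]["followup"] = vars(payload["profile"]["followup"])
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class PipelineResult:
    corpus: Corpus
    links: List[LinkageResult]
    flagsets: List[FlagSet]
    flags: pd.DataFrame  # adjudicated (endophthalmitis = postoperative)
    calls: List[AnesthesiaCall]
    anesthesia: AnesthesiaSummary
    temporal: List[TemporalClassification]
    followup: FollowupSummary
    report: SafetyReport
    audit: Optional[AuditResult]


def flag_corpus(corpus: Corpus, lexicon: Optional[TermLexicon] = None,
                case_ids: Optional[Sequence[str]] = None) -> List[FlagSet]:
    """Run the complication flagger over every case of a corpus."""
    lexicon = lexicon or default_lexicon()
    by_case = corpus.docs_by_case()
    keep = set(case_ids) if case_ids is not None else None
    out = []
    for case in corpus.manifest:
        if keep is not None and case.case_id not in keep:
            continue
        out.append(flag_case(case, by_case[case.case_id], lexicon))
    return out


def temporal_stage(corpus: Corpus, flagsets: Sequence[FlagSet]):
    """Endophthalmitis adjudication + follow-up arithmetic."""
    doc_dates = {d.doc_id: d.date for d in corpus.documents}
    by_id = {c.case_id: c for c in corpus.manifest}
    classifications = []
    for fs in flagsets:
        dated = [
            DatedMention(mention=m, date=doc_dates.get(m.doc_id))
            for m in fs.mentions if m.term == "endophthalmitis"
        ]
        classifications.append(classify_endophthalmitis(by_id[fs.case_id], dated))
    followup = followup_summary(corpus.manifest, corpus.documents)
    return classifications, followup


def anesthesia_stage(corpus: Corpus,
                     resolutions: Optional[Mapping[str, str]] = None):
    """Classify every case's anesthesia section and summarize.

    When ``resolutions`` is omitted and planted truth is present, the
    truth's labels resolve needs-review cases (synthetic stand-in for
    the study's manual verification).
    """
    alex = default_anesthesia_lexicon()
    reports = {
        d.case_id: d for d in corpus.documents if d.kind == "operative_report"
    }
    calls = []
    for case in corpus.manifest:
        report = reports.get(case.case_id)
        if report is None:
            raise PipelineError(f"case {case.case_id}: no operative report")
        text = extract_anesthesia_text(report)
        calls.append(classify(text, report.body, alex, case_id=case.case_id))
    if resolutions is None:
        resolutions = {
            cid: gt.anesthesia_true
            for cid, gt in corpus.truth_by_case().items()
        }
    return calls, summarize(calls, resolutions)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full workflow and (optionally) serialize every stage."""
    out_dir = Path(config.out_dir)
    if config.profile is not None:
        profile = config.profile.with_seed(config.seed)
        corpus = generate_corpus(profile, adversarial=config.adversarial)
    else:
        if config.manifest_path is None or config.docs_path is None:
            raise PipelineError("provide either a profile or input paths")
        corpus = read_corpus(config.manifest_path, config.docs_path,
                             config.truth_path)
    if not corpus.manifest:
        raise PipelineError("no cases in manifest")

    links = link_all(corpus.manifest, corpus.documents)
    unresolved = [l.case_id for l in links if l.status == "unresolved"]
    if unresolved:
        if config.strict_linkage:
            raise PipelineError(
                f"unresolved linkage for cases: {', '.join(unresolved)}"
            )
        log.warning("excluding %d unresolved cases: %s", len(unresolved),
                    ", ".join(unresolved))
    linked_ids = [l.case_id for l in links if l.status != "unresolved"]

    flagsets = flag_corpus(corpus, config.lexicon, case_ids=linked_ids)
    keep = set(linked_ids)
    sub_manifest = [c for c in corpus.manifest if c.case_id in keep]
    sub = Corpus(manifest=sub_manifest, documents=corpus.documents)

    classifications, followup = temporal_stage(sub, flagsets)
    calls, anes_summary = anesthesia_stage(sub)
    report = complication_report(flagsets, classifications,
                                 anesthesia_summary=anes_summary,
                                 followup=followup)

    truths = sub.truth_by_case()
    audit = None
    if truths:
        adjudicated = flag_table(flagsets, classifications)
        reviewer = truth_table(truths).loc[adjudicated.index]
        audit = run_audit(adjudicated, reviewer, config.audit_fraction,
                          seed=config.seed)
    else:
        adjudicated = flag_table(flagsets, classifications)

    result = PipelineResult(
        corpus=corpus, links=links, flagsets=flagsets, flags=adjudicated,
        calls=calls, anesthesia=anes_summary, temporal=classifications,
        followup=followup, report=report, audit=audit,
    )
    if config.write_outputs:
        _write_outputs(config, result, out_dir)
    return result


# ----------------------------------------------------------------- output --

def _provenance(config: PipelineConfig) -> Dict[str, object]:
    return {"seed": config.seed, "config_sha256": config.digest(),
            "actap_version": _version}


def _prov_comment(config: PipelineConfig) -> str:
    p = _provenance(config)
    return f"# seed={p['seed']} config_sha256={p['config_sha256']} actap={p['actap_version']}\n"


def _write_json(path: Path, obj: dict, config: PipelineConfig) -> None:
    obj = {"_provenance": _provenance(config), **obj}
    path.write_text(json.dumps(obj, indent=2, default=str) + "\n")


def _write_outputs(config: PipelineConfig, res: PipelineResult,
                   out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    prov = _prov_comment(config)
    if config.profile is not None:
        write_corpus(res.corpus, out_dir)

    links_df = pd.DataFrame(
        {
            "case_id": [l.case_id for l in res.links],
            "status": [l.status for l in res.links],
            "discrepant_fields": ["|".join(l.discrepant_fields) for l in res.links],
            "resolution_note": [l.resolution_note for l in res.links],
        }
    )
    _write_csv(out_dir / "links.csv", links_df, prov)

    terms = list(res.flags.columns)
    flag_rows = []
    for fs in res.flagsets:
        row = {"case_id": fs.case_id}
        row.update({t: int(fs.flags.get(t, False)) for t in terms})
        evidence = [m.excerpt for m in fs.mentions if not m.negated]
        row["evidence"] = " | ".join(evidence)
        flag_rows.append(row)
    _write_csv(out_dir / "flags.csv", pd.DataFrame(flag_rows), prov)

    with open(out_dir / "mentions.jsonl", "w", encoding="utf-8") as fh:
        fh.write(prov)
        for fs in res.flagsets:
            for m in fs.mentions:
                fh.write(json.dumps({
                    "case_id": fs.case_id, "doc_id": m.doc_id, "term": m.term,
                    "start": m.start, "end": m.end, "negated": m.negated,
                    "excerpt": m.excerpt,
                }) + "\n")

    calls_df = pd.DataFrame(
        {
            "case_id": [c.case_id for c in res.calls],
            "matched_terms": ["|".join(sorted(c.matched_terms)) for c in res.calls],
            "auto_label": [c.auto_label for c in res.calls],
            "no_hit": [int(c.no_hit) for c in res.calls],
            "needs_review": [int(c.needs_review) for c in res.calls],
            "review_reason": [c.review_reason for c in res.calls],
            "final_label": [c.final_label for c in res.calls],
        }
    )
    _write_csv(out_dir / "anesthesia.csv", calls_df, prov)
    _write_json(out_dir / "anesthesia_summary.json", vars(res.anesthesia).copy(),
                config)

    temporal_df = pd.DataFrame(
        {
            "case_id": [t.case_id for t in res.temporal],
            "n_mentions": [t.n_mentions for t in res.temporal],
            "earliest_mention_date": [
                t.earliest_mention_date.isoformat() if t.earliest_mention_date
                else "" for t in res.temporal
            ],
            "classification": [t.classification for t in res.temporal],
        }
    )
    _write_csv(out_dir / "temporal.csv", temporal_df, prov)
    _write_json(
        out_dir / "temporal.json",
        {
            "endophthalmitis": {
                "cases_with_mentions": sum(
                    t.classification != "none" for t in res.temporal
                ),
                "preexisting_only": sum(
                    t.classification == "preexisting_only" for t in res.temporal
                ),
                "postoperative": sum(
                    t.classification == "postoperative" for t in res.temporal
                ),
            },
            "followup": {
                "n": res.followup.n,
                "day1_count": res.followup.day1_count,
                "retention_counts": res.followup.retention_counts,
                "retention_any_visit_counts":
                    res.followup.retention_any_visit_counts,
                "median_days": res.followup.median_days,
                "min_days": res.followup.min_days,
                "max_days": res.followup.max_days,
            },
        },
        config,
    )

    _write_csv(out_dir / "report_table.csv", res.report.to_frame(), prov)
    _write_json(
        out_dir / "safety_report.json",
        {
            "n": res.report.n,
            "rows": [vars(r).copy() for r in res.report.rows],
            "total": vars(res.report.total).copy(),
            "postoperative_endophthalmitis":
                res.report.postoperative_endophthalmitis,
        },
        config,
    )
    if res.audit is not None:
        audit_obj = vars(res.audit).copy()
        _write_json(out_dir / "audit.json", audit_obj, config)

    _write_json(
        out_dir / "run_manifest.json",
        {
            "n_cases": len(res.corpus.manifest),
            "n_documents": len(res.corpus.documents),
            "outputs": sorted(p.name for p in out_dir.iterdir() if p.is_file()),
        },
        config,
    )


def _write_csv(path: Path, df: pd.DataFrame, prov: str) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(prov)
        df.to_csv(fh, index=False)
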