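"""Cohort safety report and the validation-audit procedure.

Complication rates are reported with exact (Clopper–Pearson) binomial
95% intervals, which remain meaningful for the 0- and 1-event counts
this kind of surveillance produces. The endophthalmitis row counts only
postoperative cases (temporal adjudication); all other rows come from
the adjudicated free-text flags, grouped into display categories.

The audit draws a seeded uniform random sample of cases without
replacement and scores the flag table against a reviewer table — in
synthetic runs, the planted ground truth stands in for the manual
chart reviewer. A case agrees when its entire complication flag vector
matches the reviewer's.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .records import GroundTruth
from .temporal import TemporalClassification
from .textflag import DEFAULT_COMPLICATION_TERMS, FlagSet

__all__ = [
    "clopper_pearson",
    "ComplicationRow",
    "SafetyReport",
    "AuditResult",
    "flag_table",
    "truth_table",
    "complication_report",
    "run_audit",
    "REPORT_ROWS",
]

#: Display rows and the lexicon terms feeding each (endophthalmitis is
#: temporal-adjudicated). "hemorrhage"/"bleeding" fold into the Hyphema
#: row unless "suprachoroidal" is also flagged for the case.
REPORT_ROWS: Tuple[Tuple[str, Tuple[str, ...]], ...] = (
    ("Endophthalmitis", ("endophthalmitis",)),
    ("Lens touch/trauma", ("lens touch",)),
    ("Iris touch/trauma", ("iris touch",)),
    ("Hyphema", ("hyphema", "bleeding", "hemorrhage")),
    ("Descemet membrane tear", ("tear",)),
    ("Other corneal trauma", ("cornea touch",)),
    ("Entry site leak", ("leak",)),
    ("Anterior chamber shallowing forcing termination of fluid collection",
     ("shallow",)),
    ("Suprachoroidal hemorrhage", ("suprachoroidal",)),
    ("Problems caused by patient's movements", ("movement",)),
)


def clopper_pearson(k: int, n: int, alpha: float = 0.05) -> Tuple[float, float]:
    """Exact binomial confidence interval for ``k`` events in ``n`` trials.

    Beta-quantile form: lower = B(alpha/2; k, n-k+1), upper =
    B(1-alpha/2; k+1, n-k), with the conventional 0 and 1 endpoints at
    k = 0 and k = n.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError("k must be in [0, n]")
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def _format_rate(pct: float) -> str:
    """Display rounding: 2 decimal places below 1%, else 1 decimal."""
    if pct == 0:
        return "0"
    if pct < 1:
        return f"{pct:.2f}"
    return f"{pct:.1f}"


@dataclass
class ComplicationRow:
    name: str
    count: int
    rate_pct: float
    ci_low_pct: float
    ci_high_pct: float

    @property
    def display_rate(self) -> str:
        return _format_rate(self.rate_pct)


@dataclass
class SafetyReport:
    n: int
    rows: List[ComplicationRow]
    total: ComplicationRow
    postoperative_endophthalmitis: int
    anesthesia_summary: Optional[object] = None
    followup: Optional[object] = None

    def to_frame(self) -> pd.DataFrame:
        rows = self.rows + [self.total]
        return pd.DataFrame(
            {
                "complication": [r.name for r in rows],
                "count": [r.count for r in rows],
                "rate_pct": [round(r.rate_pct, 4) for r in rows],
                "ci95_low_pct": [round(r.ci_low_pct, 4) for r in rows],
                "ci95_high_pct": [round(r.ci_high_pct, 4) for r in rows],
                "display": [f"{r.count} ({r.display_rate}%)" for r in rows],
            }
        )


def flag_table(
    flags: Sequence[FlagSet],
    temporal: Optional[Sequence[TemporalClassification]] = None,
    terms: Sequence[str] = DEFAULT_COMPLICATION_TERMS,
) -> pd.DataFrame:
    """Case-by-term boolean table; endophthalmitis adjudicated when
    temporal classifications are supplied (postoperative only)."""
    df = pd.DataFrame(
        [{t: bool(fs.flags.get(t, False)) for t in terms} for fs in flags],
        index=pd.Index([fs.case_id for fs in flags], name="case_id"),
    )
    if temporal is not None and "endophthalmitis" in df.columns:
        post = {t.case_id: t.classification == "postoperative" for t in temporal}
        df["endophthalmitis"] = [post.get(cid, False) for cid in df.index]
    return df


def truth_table(
    truths: Mapping[str, GroundTruth],
    terms: Sequence[str] = DEFAULT_COMPLICATION_TERMS,
) -> pd.DataFrame:
    """Reviewer table from planted ground truth (true complications only;
    a pre-existing endophthalmitis history is not a complication)."""
    return pd.DataFrame(
        [{t: t in gt.complications_true for t in terms} for gt in truths.values()],
        index=pd.Index(list(truths.keys()), name="case_id"),
    )


def _row_counts(adjudicated: pd.DataFrame) -> Dict[str, int]:
    counts = {name: 0 for name, _ in REPORT_ROWS}
    for _, case in adjudicated.iterrows():
        flagged = {t for t, v in case.items() if v}
        if not flagged:
            continue
        for name, terms in REPORT_ROWS:
            terms = set(terms)
            if name == "Hyphema" and "suprachoroidal" in flagged:
                terms -= {"hemorrhage", "bleeding"}
            if terms & flagged:
                counts[name] += 1
    return counts


def complication_report(
    flags: Sequence[FlagSet],
    temporal: Sequence[TemporalClassification],
    alpha: float = 0.05,
    anesthesia_summary=None,
    followup=None,
) -> SafetyReport:
    """Per-complication counts and exact-interval rates for a cohort."""
    n = len(flags)
    if n == 0:
        raise ValueError("cannot build a safety report for n == 0 cases")
    adjudicated = flag_table(flags, temporal)
    counts = _row_counts(adjudicated)

    def make_row(name: str, k: int) -> ComplicationRow:
        lo, hi = clopper_pearson(k, n, alpha)
        return ComplicationRow(
            name=name, count=k, rate_pct=100.0 * k / n,
            ci_low_pct=100.0 * lo, ci_high_pct=100.0 * hi,
        )

    rows = [make_row(name, counts[name]) for name, _ in REPORT_ROWS]
    total_count = int(adjudicated.any(axis=1).sum())
    total = make_row(f"Total ({n} biopsies)", total_count)
    post = sum(t.classification == "postoperative" for t in temporal)
    return SafetyReport(
        n=n, rows=rows, total=total, postoperative_endophthalmitis=post,
        anesthesia_summary=anesthesia_summary, followup=followup,
    )


@dataclass
class AuditResult:
    audit_n: int
    audit_fraction: float
    sampled_case_ids: List[str]
    per_flag_accuracy: Dict[str, float]
    false_positives: Dict[str, int]
    false_negatives: Dict[str, int]
    overall_accuracy: float
    disagreements: int


def run_audit(
    flags: pd.DataFrame,
    reviewer: pd.DataFrame,
    audit_fraction: float,
    seed: int,
) -> AuditResult:
    """Score the flag table against the reviewer table on a random sample.

    ``round(audit_fraction * n)`` cases are drawn uniformly without
    replacement (deterministic given ``seed``). Overall accuracy is the
    fraction of sampled cases whose full flag vector agrees.
    """
    if not 0.0 < audit_fraction <= 1.0:
        raise ValueError("audit_fraction must be in (0, 1]")
    n = len(flags)
    if n == 0:
        raise ValueError("cannot audit an empty flag table")
    reviewer = reviewer.loc[flags.index, flags.columns]
    m = max(1, round(audit_fraction * n))
    rng = np.random.default_rng(seed)
    pick = np.sort(rng.choice(n, size=m, replace=False))
    sampled = flags.index[pick]
    f = flags.loc[sampled]
    r = reviewer.loc[sampled]
    agree_matrix = f.values == r.values
    per_flag = {
        col: float(agree_matrix[:, j].mean())
        for j, col in enumerate(flags.columns)
    }
    fp = {
        col: int((f[col] & ~r[col]).sum()) for col in flags.columns
    }
    fn = {
        col: int((~f[col] & r[col]).sum()) for col in flags.columns
    }
    case_agree = agree_matrix.all(axis=1)
    return AuditResult(
        audit_n=m,
        audit_fraction=audit_fraction,
        sampled_case_ids=list(sampled),
        per_flag_accuracy=per_flag,
        false_positives=fp,
        false_negatives=fn,
        overall_accuracy=float(case_agree.mean()),
        disagreements=int((~case_agree).sum()),
    )
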