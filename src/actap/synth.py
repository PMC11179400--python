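"""Seeded synthetic EHR corpus generator.

Emits a biobank manifest plus a JSON-lines-serializable document corpus
whose composition matches a :class:`~actap.profile.CohortProfile`
exactly: category counts (anesthesia labels, documentation ambiguities,
identifier entry errors, pre-existing endophthalmitis histories, true
complications, follow-up retention) are *assigned*, not sampled, so two
corpora from the same profile differ only in surface realization
(names, dates, template choices), and every count downstream stages
should recover is planted deterministically.

Textual phenomena emulated:

* operative reports whose negative-findings paragraph explicitly negates
  every complication search phrase ("there was no lens touch ...");
* one (by default) true complication with affirmative language ("a small
  descemet membrane tear was noted adjacent to the paracentesis");
* anesthesia sections that are empty or carry only non-informative text
  ("monitored anesthesia care") for the planted no-hit cases;
* imprecise "transient general anesthesia" phrasing with intravenous
  sedation for cases truly under local anesthesia;
* clinical notes dated before the biopsy mentioning endophthalmitis for
  the planted pre-existing histories;
* manifest identifier corruption (missing leading MRN zero, wrong DOB,
  misspelled surname) with the true values on the EHR document side.

Ground truth is attached to each manifest row and serialized to a
sidecar never read by the pipeline proper.
"""

from __future__ import annotations

from datetime import date, timedelta
from importlib import resources
from typing import Dict, List, Optional, Sequence, Set

import numpy as np
import yaml

from .profile import CohortProfile, LOCAL_LABELS, RetentionSchedule
from .records import CaseRecord, Corpus, Document, GroundTruth
from .textflag import TermLexicon, default_lexicon, flag_case

__all__ = ["generate_corpus", "load_templates", "self_check", "plan_last_offsets"]

_GIVEN_NAMES = (
    "james", "mary", "robert", "patricia", "john", "jennifer", "michael",
    "linda", "david", "elizabeth", "william", "barbara", "richard", "susan",
    "joseph", "jessica", "thomas", "sarah", "charles", "karen", "daniel",
    "lisa", "matthew", "nancy", "anthony", "betty", "mark", "margaret",
    "donald", "sandra", "steven", "ashley", "paul", "kimberly", "andrew",
    "emily", "joshua", "donna", "kenneth", "michelle",
)

_SURNAMES = (
    "smith", "johnson", "williams", "brown", "jones", "garcia", "miller",
    "davis", "rodriguez", "martinez", "hernandez", "lopez", "gonzalez",
    "wilson", "anderson", "thomas", "taylor", "moore", "jackson", "martin",
    "lee", "perez", "thompson", "white", "harris", "sanchez", "clark",
    "ramirez", "lewis", "robinson", "walker", "young", "allen", "king",
    "wright", "scott", "torres", "nguyen", "hill", "flores", "green",
    "adams", "nelson", "baker", "hall", "rivera", "campbell", "mitchell",
    "carter", "roberts", "gomez", "phillips", "evans", "turner", "diaz",
    "parker", "cruz", "edwards", "collins", "reyes",
)

_PROC_START = date(2018, 1, 1)
_PROC_DAYS = 2191  # through 2023-12-31
_DOB_START = date(1930, 1, 1)
_DOB_DAYS = 27027  # through 2003-12-31

_MISUSE_PREFERENCE = ("topical", "peribulbar", "subtenon", "retrobulbar")
_ADVERSARIAL_FRACTION = 0.05


def load_templates() -> dict:
    """The packaged narrative templates (user-replaceable via the config)."""
    return yaml.safe_load(
        resources.files("actap.data").joinpath("templates.yaml").read_text()
    )


def _pick(rng: np.random.Generator, options: Sequence[str]) -> str:
    return options[int(rng.integers(0, len(options)))]


def _sample(rng: np.random.Generator, pool: Sequence[int], k: int) -> List[int]:
    if k == 0:
        return []
    idx = rng.choice(len(pool), size=k, replace=False)
    return [int(pool[i]) for i in idx]


def _expand_counts(pairs) -> List[str]:
    out: List[str] = []
    for label, count in pairs:
        out.extend([label] * int(count))
    return out


def _reorder(rng: np.random.Generator, items: list) -> list:
    perm = rng.permutation(len(items))
    return [items[int(i)] for i in perm]


def plan_last_offsets(
    schedule: RetentionSchedule, n: int, rng: np.random.Generator
) -> List[int]:
    """Plant per-case last-visit day offsets matching the retention schedule.

    Window counts are exact (``round(fraction * n)``); within the >=90-day
    block the values are shaped so the cohort median equals
    ``schedule.median_days`` and the maximum equals ``schedule.max_days``
    whenever the block is large enough, otherwise sampled uniformly.
    """
    if n == 0:
        return []
    c_day1 = round(schedule.day1 * n)
    c_week = round(schedule.week1 * n)
    c_month = round(schedule.month1 * n)
    c_quarter = round(schedule.month3 * n)
    zeros = n - c_day1
    b1, b7, b30 = c_day1 - c_week, c_week - c_month, c_month - c_quarter
    offsets = (
        [0] * zeros
        + [int(v) for v in rng.integers(1, 7, size=b1)]
        + [int(v) for v in rng.integers(7, 30, size=b7)]
        + [int(v) for v in rng.integers(30, 90, size=b30)]
        + _block_90(schedule, n, c_quarter, rng)
    )
    return _reorder(rng, offsets)


def _block_90(schedule, n, b90, rng) -> List[int]:
    if b90 == 0:
        return []
    med, mx = schedule.median_days, schedule.max_days
    m1 = (n + 1) // 2 if n % 2 else n // 2  # sorted rank(s) of the median
    m2 = m1 if n % 2 else n // 2 + 1
    start_rank = n - b90 + 1
    if 90 < med < mx and m1 >= start_rank:
        k_below = m1 - start_rank
        n_med = m2 - m1 + 1
        k_above = b90 - k_below - n_med
        if k_above >= 1:
            below = [int(v) for v in rng.integers(90, med, size=k_below)]
            above = [int(v) for v in rng.integers(med + 1, mx, size=k_above - 1)]
            return below + [med] * n_med + above + [mx]
    if mx > 90:
        return [int(v) for v in rng.integers(90, mx, size=b90 - 1)] + [mx]
    return [90] * b90


def _visit_days(last: int) -> List[int]:
    if last <= 0:
        return [0]
    days = {1, last}
    days.update(w for w in (7, 30, 90) if w < last)
    return sorted(days)


def _corrupt_dob(d: date) -> date:
    if d.day <= 12 and d.day != d.month:
        return d.replace(month=d.day, day=d.month)
    return d.replace(day=d.day - 1 if d.day > 1 else d.day + 1)


def _corrupt_name(name: str) -> str:
    given, surname = name.split(" ", 1)
    ch = "x" if surname[1] != "x" else "y"
    return f"{given} {surname[0]}{ch}{surname[2:]}"


def _fresh_low_mrn(rng: np.random.Generator, used: Set[int]) -> int:
    while True:
        v = int(rng.integers(1, 1_000_000))
        if v not in used:
            used.add(v)
            return v


def generate_corpus(
    profile: CohortProfile,
    adversarial: bool = False,
    templates: Optional[dict] = None,
) -> Corpus:
    """Generate a (manifest, documents) corpus with exact planted counts.

    Deterministic given ``profile`` (including its seed). With
    ``adversarial`` enabled, benign uses of ambiguous terms ("tear
    film", "leak-free wound") are injected into a small fraction of
    non-complicated reports; planted ground truth is unchanged, so the
    resulting flag/truth disagreements quantify the false-positive cost
    of such language.
    """
    profile.validate()
    n = profile.n_cases
    if n == 0:
        return Corpus(manifest=[], documents=[])
    tpl = templates or load_templates()
    rng = np.random.default_rng(profile.seed)

    # --- patients -------------------------------------------------------
    used_mrn: Set[int] = set()
    mrn_vals = [int(v) + 1 for v in rng.choice(9_999_998, size=profile.n_patients,
                                               replace=False)]
    used_mrn.update(mrn_vals)
    patients = []
    for i in range(profile.n_patients):
        name = f"{_pick(rng, _GIVEN_NAMES)} {_pick(rng, _SURNAMES)}"
        dob = _DOB_START + timedelta(days=int(rng.integers(0, _DOB_DAYS + 1)))
        patients.append({"mrn": mrn_vals[i], "name": name, "dob": dob})

    owners = list(range(profile.n_patients)) + _sample(
        rng, list(range(profile.n_patients)), n - profile.n_patients
    )
    owners = _reorder(rng, owners)

    # --- per-case categorical assignments (exact counts) ---------------
    diagnoses = _reorder(rng, _expand_counts(profile.diagnosis_mix))
    anes_true = _reorder(
        rng, _expand_counts(sorted(profile.anesthesia_mix.items()))
    )

    by_label: Dict[str, List[int]] = {}
    for i, lbl in enumerate(anes_true):
        by_label.setdefault(lbl, []).append(i)

    misuse_pool: List[int] = []
    for lbl in _MISUSE_PREFERENCE:
        misuse_pool.extend(by_label.get(lbl, []))
    misuse_set = set(_sample(rng, misuse_pool, profile.n_general_misuse))

    nohit_pool = [
        i for i in range(n)
        if anes_true[i] != "general" and i not in misuse_set
    ]
    nohit_set = set(_sample(rng, nohit_pool, profile.n_no_hit_anesthesia))

    endo_diag = [i for i, dx in enumerate(diagnoses) if dx == "endophthalmitis"]
    pre_endo = list(endo_diag[: profile.n_preexisting_endophthalmitis])
    extra_needed = profile.n_preexisting_endophthalmitis - len(pre_endo)
    if extra_needed > 0:
        others = [i for i in range(n) if i not in set(pre_endo)]
        pre_endo.extend(_sample(rng, others, extra_needed))
    pre_endo_set = set(pre_endo)

    comp_set = set(_sample(rng, list(range(n)), profile.n_true_complications))

    corrupt_cases = _sample(rng, list(range(n)), profile.n_identifier_mismatches)
    corruption_kind = {
        ci: ("mrn_leading_zero", "dob_wrong", "name_misspelled")[j % 3]
        for j, ci in enumerate(corrupt_cases)
    }
    # MRN-corruption requires the true MRN to carry a leading zero
    for ci, kind in corruption_kind.items():
        if kind == "mrn_leading_zero":
            patients[owners[ci]]["mrn"] = _fresh_low_mrn(rng, used_mrn)

    adv_set: Set[int] = set()
    if adversarial:
        n_adv = max(1, round(_ADVERSARIAL_FRACTION * n))
        adv_pool = [i for i in range(n) if i not in comp_set]
        adv_set = set(_sample(rng, adv_pool, min(n_adv, len(adv_pool))))

    # --- surgeons / technique -------------------------------------------
    base, rem = divmod(n, profile.n_surgeons)
    surgeon_counts = [base + (1 if s < rem else 0) for s in range(profile.n_surgeons)]
    needle_target = round(profile.technique_needle_fraction * n)
    surgeon_tech, cum = [], 0
    for count in surgeon_counts:
        surgeon_tech.append("needle" if cum < needle_target else "cannula")
        cum += count
    surgeon_of_case, tech_of_case = [], []
    for s, count in enumerate(surgeon_counts):
        surgeon_of_case.extend([f"S{s + 1:02d}"] * count)
        tech_of_case.extend([surgeon_tech[s]] * count)

    last_offsets = plan_last_offsets(profile.followup, n, rng)

    # --- procedure dates (distinct per patient) -------------------------
    taken: Dict[int, Set[int]] = {}
    proc_days: List[int] = []
    for i in range(n):
        owner = owners[i]
        seen = taken.setdefault(owner, set())
        while True:
            d = int(rng.integers(0, _PROC_DAYS + 1))
            if d not in seen:
                seen.add(d)
                proc_days.append(d)
                break

    # --- assemble cases and documents -----------------------------------
    op_tpl = tpl["op_report"]
    note_tpl = tpl["clinical_note"]
    anes_tpl = tpl["anesthesia_section"]
    manifest: List[CaseRecord] = []
    documents: List[Document] = []

    for i in range(n):
        case_id = f"AH{i + 1:05d}"
        patient = patients[owners[i]]
        mrn_str = f"{patient['mrn']:07d}"
        proc_date = _PROC_START + timedelta(days=proc_days[i])
        laterality = "OD" if int(rng.integers(0, 2)) == 0 else "OS"
        eye = "right" if laterality == "OD" else "left"
        label = anes_true[i]
        is_misuse = i in misuse_set
        is_nohit = i in nohit_set

        if is_nohit:
            anesthesia_text = _pick(rng, anes_tpl["no_hit"])
        elif is_misuse:
            anesthesia_text = _pick(rng, anes_tpl["misuse"]).format(local=label)
        else:
            anesthesia_text = _pick(rng, anes_tpl[label])

        if i in comp_set:
            tear_sentence = _pick(rng, op_tpl["tear_affirmative"])
            complications = frozenset({"tear"})
        else:
            tear_sentence = _pick(rng, op_tpl["tear_negative"])
            complications = frozenset()

        parts = [
            _pick(rng, op_tpl["opening"]).format(eye=eye),
            _pick(rng, op_tpl["biopsy"][tech_of_case[i]]),
            _pick(rng, op_tpl["negative_findings"]).format(
                tear_sentence=tear_sentence
            ),
        ]
        if is_nohit:
            parts.append(
                _pick(rng, op_tpl["body_anesthesia_note"]).format(label=label)
            )
        parts.append(_pick(rng, op_tpl["closing"]))
        if i in adv_set:
            parts.append(_pick(rng, tpl["adversarial"]))
        body = " ".join(parts)

        documents.append(
            Document(
                doc_id=f"{case_id}-OP",
                case_id=case_id,
                kind="operative_report",
                date=proc_date,
                body=body,
                anesthesia_text=anesthesia_text,
                patient_mrn=mrn_str,
                patient_name=patient["name"],
                patient_dob=patient["dob"],
            )
        )

        visit_days = _visit_days(last_offsets[i])
        for k, day in enumerate(visit_days):
            documents.append(
                Document(
                    doc_id=f"{case_id}-N{k + 1:02d}",
                    case_id=case_id,
                    kind="clinical_note",
                    date=proc_date + timedelta(days=day),
                    body=_pick(rng, note_tpl["routine"]).format(day=day, eye=eye),
                    patient_mrn=mrn_str,
                    patient_name=patient["name"],
                    patient_dob=patient["dob"],
                )
            )
        if i in pre_endo_set:
            back = int(rng.integers(365, 1826))
            documents.append(
                Document(
                    doc_id=f"{case_id}-N00",
                    case_id=case_id,
                    kind="clinical_note",
                    date=proc_date - timedelta(days=back),
                    body=_pick(rng, note_tpl["preexisting_endophthalmitis"]).format(
                        eye=eye
                    ),
                    patient_mrn=mrn_str,
                    patient_name=patient["name"],
                    patient_dob=patient["dob"],
                )
            )

        truth = GroundTruth(
            anesthesia_true=label,
            anesthesia_section_present=bool(anesthesia_text),
            general_misuse=is_misuse,
            complications_true=complications,
            has_preexisting_endophthalmitis=i in pre_endo_set,
            identifier_corruption=corruption_kind.get(i, "none"),
            followup_days=tuple(visit_days),
        )

        man_mrn, man_name, man_dob = mrn_str, patient["name"], patient["dob"]
        kind = corruption_kind.get(i)
        if kind == "mrn_leading_zero":
            man_mrn = mrn_str[1:]  # drop exactly the one leading zero
        elif kind == "dob_wrong":
            man_dob = _corrupt_dob(man_dob)
        elif kind == "name_misspelled":
            man_name = _corrupt_name(man_name)

        manifest.append(
            CaseRecord(
                case_id=case_id,
                mrn=man_mrn,
                name=man_name,
                dob=man_dob,
                procedure_date=proc_date,
                laterality=laterality,
                surgeon_id=surgeon_of_case[i],
                technique=tech_of_case[i],
                primary_diagnosis=diagnoses[i],
                truth=truth,
            )
        )

    return Corpus(manifest=manifest, documents=documents)


def self_check(corpus: Corpus, lexicon: Optional[TermLexicon] = None) -> None:
    """Template-soundness check: flagging the corpus recovers planted truth.

    For every case, running the complication flagger over its documents
    must yield exactly the planted complication set (with the raw
    endophthalmitis flag matching the planted pre-existing history).
    Raises ``AssertionError`` listing the first discrepancies.
    """
    lex = lexicon or default_lexicon()
    by_case = corpus.docs_by_case()
    bad = []
    for case in corpus.manifest:
        fs = flag_case(case, by_case[case.case_id], lex)
        truth = case.truth
        for term, flagged in fs.flags.items():
            if term == "endophthalmitis":
                want = truth.has_preexisting_endophthalmitis or (
                    term in truth.complications_true
                )
            else:
                want = term in truth.complications_true
            if flagged != want:
                bad.append((case.case_id, term, flagged, want))
    if bad:
        raise AssertionError(f"generator self-check failed for {bad[:10]}")
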