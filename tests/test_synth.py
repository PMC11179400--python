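"""Generator tests: planted-count conservation, determinism, template soundness."""

import dataclasses

import numpy as np
import pytest

from actap import ProfileError, default_lexicon, default_profile, generate_corpus
from actap.io import documents_jsonl_bytes, manifest_csv_bytes
from actap.pipeline import flag_corpus
from actap.records import Corpus
from actap.synth import plan_last_offsets, self_check

from .conftest import make_small_profile, random_profile


class TestDefaultProfile:
    def test_cohort_headline_composition(self):
        p = default_profile()
        assert p.n_cases == 1418
        assert p.n_patients == 1154
        assert p.n_surgeons == 17
        assert p.anesthesia_mix == {
            "topical": 1021, "peribulbar": 125, "subtenon": 61,
            "retrobulbar": 147, "general": 64,
        }
        assert p.n_true_complications == 1
        assert p.n_no_hit_anesthesia == 50
        assert (p.n_general_term_total, p.n_general_misuse) == (104, 40)
        assert p.n_identifier_mismatches == 14
        assert p.n_preexisting_endophthalmitis == 14
        assert sum(c for _, c in p.diagnosis_mix) == 1418
        assert dict(p.diagnosis_mix)["cataract"] == 711
        p.validate()

    @pytest.mark.parametrize(
        "override,field",
        [
            ({"n_cases": 121}, "diagnosis_mix"),
            ({"anesthesia_mix": {"topical": 1}}, "anesthesia_mix"),
            ({"n_general_misuse": 200}, "n_general_misuse"),
            ({"n_no_hit_anesthesia": 5000}, "n_no_hit"),
            ({"n_patients": 10}, "n_patients"),
            ({"technique_needle_fraction": 1.5}, "technique_needle_fraction"),
            ({"n_true_complications": -1}, "n_true_complications"),
        ],
    )
    def test_invalid_profiles_name_the_field(self, override, field):
        p = dataclasses.replace(make_small_profile(), **override)
        with pytest.raises(ProfileError, match=field):
            p.validate()

    def test_retention_must_be_monotone(self):
        p = make_small_profile()
        bad = dataclasses.replace(
            p, followup=dataclasses.replace(p.followup, week1=0.2)
        )
        with pytest.raises(ProfileError, match="non-increasing"):
            bad.validate()


class TestGenerateCorpus:
    def test_empty_profile_gives_empty_corpus(self):
        p = dataclasses.replace(
            make_small_profile(), n_cases=0, n_patients=0,
            diagnosis_mix=(), anesthesia_mix={},
            n_no_hit_anesthesia=0, n_general_term_total=0, n_general_misuse=0,
            n_preexisting_endophthalmitis=0, n_true_complications=0,
            n_identifier_mismatches=0,
        )
        corpus = generate_corpus(p)
        assert corpus.manifest == [] and corpus.documents == []

    def test_invalid_profile_rejected(self):
        p = dataclasses.replace(make_small_profile(), n_identifier_mismatches=-2)
        with pytest.raises(ProfileError):
            generate_corpus(p)

    @pytest.mark.parametrize("seed", [0, 11, 202])
    def test_planted_count_conservation(self, seed):
        p = make_small_profile(seed=seed)
        corpus = generate_corpus(p)
        truths = [c.truth for c in corpus.manifest]
        labels = [t.anesthesia_true for t in truths]
        for label, want in p.anesthesia_mix.items():
            assert labels.count(label) == want
        assert sum(t.general_misuse for t in truths) == p.n_general_misuse
        sections = [_section(corpus, c.case_id) for c in corpus.manifest]
        assert sum(
            "general" in s for s in sections
        ) == p.n_general_term_total
        assert sum(not t.anesthesia_section_present for t in truths) <= \
            p.n_no_hit_anesthesia
        assert sum(
            t.has_preexisting_endophthalmitis for t in truths
        ) == p.n_preexisting_endophthalmitis
        assert sum(
            bool(t.complications_true) for t in truths
        ) == p.n_true_complications
        assert sum(
            t.identifier_corruption != "none" for t in truths
        ) == p.n_identifier_mismatches
        diag = [c.primary_diagnosis for c in corpus.manifest]
        for label, want in p.diagnosis_mix:
            assert diag.count(label) == want
        # one operative report per case, dated on the procedure date
        ops = [d for d in corpus.documents if d.kind == "operative_report"]
        assert len(ops) == p.n_cases
        proc = {c.case_id: c.procedure_date for c in corpus.manifest}
        assert all(d.date == proc[d.case_id] for d in ops)
        # a patient owns at most two cases; distinct patients == n_patients
        mrns = [d.patient_mrn for d in ops]
        assert len(set(mrns)) == p.n_patients

    def test_deterministic_byte_identical(self):
        p = make_small_profile(seed=42)
        c1, c2 = generate_corpus(p), generate_corpus(p)
        assert manifest_csv_bytes(c1.manifest) == manifest_csv_bytes(c2.manifest)
        assert documents_jsonl_bytes(c1.documents) == documents_jsonl_bytes(
            c2.documents
        )

    def test_seed_changes_surface_not_counts(self):
        a = generate_corpus(make_small_profile(seed=1))
        b = generate_corpus(make_small_profile(seed=2))
        assert manifest_csv_bytes(a.manifest) != manifest_csv_bytes(b.manifest)
        for corpus in (a, b):
            assert sum(
                bool(c.truth.complications_true) for c in corpus.manifest
            ) == 1

    def test_template_soundness_self_check(self):
        self_check(generate_corpus(make_small_profile(seed=5)))

    def test_adversarial_mode_injects_false_positives(self):
        p = make_small_profile(seed=5)
        corpus = generate_corpus(p, adversarial=True)
        with pytest.raises(AssertionError):
            self_check(corpus)

    def test_clean_profile_yields_all_false_flags(self):
        p = make_small_profile(
            seed=9, n_true_complications=0, n_general_misuse=0,
            n_no_hit_anesthesia=0, n_preexisting_endophthalmitis=0,
            n_identifier_mismatches=0,
        )
        corpus = generate_corpus(p)
        for fs in flag_corpus(corpus):
            assert not any(fs.flags.values())

    def test_random_profiles_conserve_counts(self):
        rng = np.random.default_rng(2024)
        for _ in range(10):
            p = random_profile(rng)
            p.validate()
            corpus = generate_corpus(p)
            assert len(corpus.manifest) == p.n_cases
            truths = [c.truth for c in corpus.manifest]
            labels = [t.anesthesia_true for t in truths]
            for label, want in p.anesthesia_mix.items():
                assert labels.count(label) == want


def _section(corpus: Corpus, case_id: str) -> str:
    for d in corpus.documents:
        if d.case_id == case_id and d.kind == "operative_report":
            return d.anesthesia_text or ""
    return ""


class TestFollowupPlanting:
    def test_default_offsets_hit_retention_and_median(self):
        p = default_profile()
        rng = np.random.default_rng(0)
        offsets = plan_last_offsets(p.followup, p.n_cases, rng)
        assert len(offsets) == 1418
        assert sum(v >= 7 for v in offsets) == 1377
        assert sum(v >= 30 for v in offsets) == 1256
        assert sum(v >= 90 for v in offsets) == 978
        assert sum(v >= 1 for v in offsets) == 1408
        assert float(np.median(offsets)) == 223.0
        assert (min(offsets), max(offsets)) == (0, 2003)
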