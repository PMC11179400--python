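"""Anesthesia-section extraction, rule-table classification, cohort summary."""

from datetime import date

import numpy as np
import pytest

from actap import (AnesthesiaLexicon, classify, default_anesthesia_lexicon,
                   extract_anesthesia_text, generate_corpus, summarize)
from actap.pipeline import anesthesia_stage
from actap.records import Document

from .conftest import make_small_profile, random_profile


@pytest.fixture(scope="module")
def lexicon():
    return default_anesthesia_lexicon()


def _report(anesthesia_text):
    return Document(doc_id="d1", case_id="C1", kind="operative_report",
                    date=date(2020, 1, 1), body="body text",
                    anesthesia_text=anesthesia_text)


class TestExtract:
    def test_passthrough(self):
        text = "topical anesthesia with intracameral lidocaine"
        assert extract_anesthesia_text(_report(text)) == text

    @pytest.mark.parametrize("empty", ["", "   ", None])
    def test_empty_is_absent(self, empty):
        assert extract_anesthesia_text(_report(empty)) is None

    def test_imprecise_text_is_still_returned(self):
        assert extract_anesthesia_text(
            _report("monitored anesthesia care")
        ) == "monitored anesthesia care"

    def test_rejects_clinical_note(self):
        note = Document(doc_id="n", case_id="C1", kind="clinical_note",
                        date=date(2020, 1, 1), body="x")
        with pytest.raises(ValueError):
            extract_anesthesia_text(note)


class TestClassify:
    def test_topical_with_adjuncts(self, lexicon):
        call = classify("topical anesthesia with intracameral lidocaine",
                        lexicon=lexicon)
        assert call.auto_label == "topical"
        assert not call.needs_review and not call.no_hit and not call.akinesia

    def test_no_hit_on_imprecise_section(self, lexicon):
        call = classify("monitored anesthesia care", lexicon=lexicon)
        assert call.no_hit and call.auto_label == "unknown"
        assert call.needs_review and call.review_reason == "no_hit"

    def test_no_hit_on_absent_section(self, lexicon):
        call = classify(None, lexicon=lexicon)
        assert call.no_hit and call.needs_review

    def test_transient_general_misuse_resolves_local(self, lexicon):
        call = classify(
            "transient general anesthesia with intravenous sedation and "
            "topical anesthetic drops", lexicon=lexicon,
        )
        assert {"general", "topical"} <= set(call.matched_terms)
        assert call.needs_review and call.review_reason == "general_ambiguous"
        assert call.auto_label == "topical" and not call.akinesia

    def test_plain_general_stays_general(self, lexicon):
        call = classify("general anesthesia with endotracheal intubation",
                        lexicon=lexicon)
        assert call.auto_label == "general" and call.akinesia
        assert not call.needs_review

    def test_block_outranks_topical(self, lexicon):
        call = classify("retrobulbar block after topical drops",
                        lexicon=lexicon)
        assert call.auto_label == "retrobulbar" and call.akinesia

    def test_adjunct_terms_alone_conflict(self, lexicon):
        call = classify("2% lidocaine given", lexicon=lexicon)
        assert call.auto_label == "unknown"
        assert call.review_reason == "conflicting_terms"

    def test_misuse_pattern_transient_window(self, lexicon):
        near = classify("transient general anesthesia; topical drops",
                        lexicon=lexicon)
        assert near.review_reason == "general_ambiguous"
        far = classify(
            "transient blur resolved and then at length general anesthesia",
            lexicon=lexicon,
        )
        assert far.auto_label == "general"

    def test_lexicon_validation(self):
        with pytest.raises(ValueError):
            AnesthesiaLexicon(terms=())
        with pytest.raises(ValueError):
            AnesthesiaLexicon(terms=("Topical",))


class TestSummarize:
    def test_single_unambiguous_case(self, lexicon):
        call = classify("topical anesthesia", lexicon=lexicon, case_id="C1")
        s = summarize([call])
        assert s.accuracy_all == 1.0
        assert s.akinesia_count == 0
        assert s.label_counts == {"topical": 1}

    def test_duplicate_case_id_rejected(self, lexicon):
        call = classify("topical anesthesia", lexicon=lexicon, case_id="C1")
        with pytest.raises(ValueError, match="duplicate"):
            summarize([call, call])

    def test_resolutions_apply_only_to_review_cases(self, lexicon):
        plain = classify("topical anesthesia", lexicon=lexicon, case_id="A")
        nohit = classify(None, lexicon=lexicon, case_id="B")
        s = summarize([plain, nohit],
                      resolutions={"A": "general", "B": "peribulbar"})
        assert plain.final_label == "topical"  # resolution ignored
        assert nohit.final_label == "peribulbar"
        assert s.accuracy_all == 0.5
        assert s.accuracy_excluding_no_hit == 1.0

    def test_small_corpus_counts_match_planting(self):
        p = make_small_profile(seed=21)
        corpus = generate_corpus(p)
        _, s = anesthesia_stage(corpus)
        assert s.no_hit_count == p.n_no_hit_anesthesia
        assert s.general_term_count == p.n_general_term_total
        assert s.general_resolved_local_count == p.n_general_misuse
        assert s.label_counts == dict(p.anesthesia_mix)
        assert s.akinesia_count == (
            p.anesthesia_mix["retrobulbar"] + p.anesthesia_mix["general"]
        )
        assert s.accuracy_non_review == 1.0

    def test_partition_on_random_profiles(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            p = random_profile(rng)
            corpus = generate_corpus(p)
            if not corpus.manifest:
                continue
            _, s = anesthesia_stage(corpus)
            assert sum(s.label_counts.values()) == p.n_cases
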