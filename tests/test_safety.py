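"""Exact binomial intervals, the safety report, and the audit procedure."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.proportion import proportion_confint

from actap.records import GroundTruth
from actap.safety import (clopper_pearson, complication_report, flag_table,
                          run_audit, truth_table)
from actap.temporal import TemporalClassification
from actap.textflag import DEFAULT_COMPLICATION_TERMS, FlagSet


def _statsmodels_ci(k, n, alpha=0.05):
    lo, hi = proportion_confint(k, n, alpha=alpha, method="beta")
    lo = 0.0 if np.isnan(lo) else float(lo)
    hi = 1.0 if np.isnan(hi) else float(hi)
    return lo, hi


class TestClopperPearson:
    @pytest.mark.parametrize("n", [10, 100, 1418])
    def test_matches_independent_beta_oracle(self, n):
        ks = sorted({0, 1, 2, 5, n // 2, n - 1, n})
        for k in ks:
            lo, hi = clopper_pearson(k, n)
            olo, ohi = _statsmodels_ci(k, n)
            assert lo == pytest.approx(olo, abs=1e-6)
            assert hi == pytest.approx(ohi, abs=1e-6)

    def test_zero_events_closed_form(self):
        # upper bound for 0/n is 1 - (alpha/2)^(1/n)
        lo, hi = clopper_pearson(0, 100)
        assert lo == 0.0
        assert hi == pytest.approx(1 - 0.025 ** (1 / 100), abs=1e-12)
        assert round(100 * hi, 2) == 3.62

    def test_one_event_in_cohort_size(self):
        lo, hi = clopper_pearson(1, 1418)
        olo, ohi = _statsmodels_ci(1, 1418)
        assert (lo, hi) == (pytest.approx(olo, abs=1e-6),
                            pytest.approx(ohi, abs=1e-6))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            clopper_pearson(1, 0)
        with pytest.raises(ValueError):
            clopper_pearson(5, 4)

    def test_coverage_near_nominal_for_rare_events(self):
        # exact CI must cover the true rate in >= 93% of simulated cohorts
        rng = np.random.default_rng(12345)
        p_true, n, reps = 0.001, 1418, 200
        covered = 0
        for k in rng.binomial(n, p_true, size=reps):
            lo, hi = clopper_pearson(int(k), n)
            covered += lo <= p_true <= hi
        assert covered / reps >= 0.93


def _flagset(case_id, flagged=()):
    flags = {t: t in flagged for t in DEFAULT_COMPLICATION_TERMS}
    return FlagSet(case_id=case_id, flags=flags)


def _none_temporal(case_ids):
    return [TemporalClassification(cid, 0, None, "none") for cid in case_ids]


class TestComplicationReport:
    def test_zero_events_in_100(self):
        ids = [f"C{i}" for i in range(100)]
        flags = [_flagset(cid) for cid in ids]
        rep = complication_report(flags, _none_temporal(ids))
        assert rep.total.count == 0 and rep.total.rate_pct == 0.0
        assert rep.total.ci_high_pct == pytest.approx(3.62, abs=0.005)

    def test_single_tear_rate_and_rows(self):
        ids = [f"C{i}" for i in range(1418)]
        flags = [_flagset(cid, ("tear",) if cid == "C7" else ())
                 for cid in ids]
        rep = complication_report(flags, _none_temporal(ids))
        by_name = {r.name: r for r in rep.rows}
        assert by_name["Descemet membrane tear"].count == 1
        assert rep.total.count == 1
        assert round(rep.total.rate_pct, 2) == 0.07
        assert by_name["Descemet membrane tear"].display_rate == "0.07"
        assert sum(r.count for r in rep.rows) == rep.total.count

    def test_postoperative_endophthalmitis_is_temporal(self):
        ids = ["A", "B"]
        # raw flag true for both, but only B is postoperative
        flags = [_flagset(cid, ("endophthalmitis",)) for cid in ids]
        temporal = [
            TemporalClassification("A", 1, None, "preexisting_only"),
            TemporalClassification("B", 1, None, "postoperative"),
        ]
        rep = complication_report(flags, temporal)
        endo = next(r for r in rep.rows if r.name == "Endophthalmitis")
        assert endo.count == 1
        assert rep.postoperative_endophthalmitis == 1

    def test_suprachoroidal_not_double_counted_as_hyphema(self):
        ids = ["A"]
        flags = [_flagset("A", ("suprachoroidal", "hemorrhage"))]
        rep = complication_report(flags, _none_temporal(ids))
        by_name = {r.name: r for r in rep.rows}
        assert by_name["Suprachoroidal hemorrhage"].count == 1
        assert by_name["Hyphema"].count == 0
        assert sum(r.count for r in rep.rows) == rep.total.count == 1

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            complication_report([], [])


def _tables(n, truth_flags=None):
    ids = [f"C{i}" for i in range(n)]
    flags = flag_table([_flagset(cid) for cid in ids])
    truths = {
        cid: GroundTruth(
            anesthesia_true="topical", anesthesia_section_present=True,
            general_misuse=False,
            complications_true=frozenset(
                (truth_flags or {}).get(cid, ())
            ),
            has_preexisting_endophthalmitis=False,
        )
        for cid in ids
    }
    return flags, truth_table(truths)


class TestRunAudit:
    def test_identical_tables_score_perfectly(self):
        flags, reviewer = _tables(60)
        res = run_audit(flags, reviewer, audit_fraction=0.5, seed=4)
        assert res.audit_n == 30
        assert res.overall_accuracy == 1.0
        assert all(v == 1.0 for v in res.per_flag_accuracy.values())

    def test_one_planted_disagreement_full_audit(self):
        flags, reviewer = _tables(100, truth_flags={"C3": ("tear",)})
        res = run_audit(flags, reviewer, audit_fraction=1.0, seed=0)
        assert res.audit_n == 100
        assert res.overall_accuracy == pytest.approx(0.99)
        assert res.false_negatives["tear"] == 1
        assert res.disagreements == 1

    def test_accuracy_identity(self):
        flags, reviewer = _tables(80, truth_flags={"C1": ("leak",),
                                                   "C2": ("hyphema",)})
        res = run_audit(flags, reviewer, audit_fraction=0.6, seed=9)
        assert res.overall_accuracy == pytest.approx(
            1 - res.disagreements / res.audit_n
        )

    def test_deterministic_given_seed(self):
        flags, reviewer = _tables(60)
        a = run_audit(flags, reviewer, 0.4, seed=7)
        b = run_audit(flags, reviewer, 0.4, seed=7)
        assert a.sampled_case_ids == b.sampled_case_ids

    @pytest.mark.parametrize("fraction", [0.0, -0.2, 1.5])
    def test_invalid_fraction_rejected(self, fraction):
        flags, reviewer = _tables(10)
        with pytest.raises(ValueError):
            run_audit(flags, reviewer, fraction, seed=0)
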