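"""Cohort profiles for the synthetic surgical biobank.

A :class:`CohortProfile` fully determines a synthetic cohort: how many
cases and patients, the anesthesia and diagnosis composition, how many
documentation ambiguities to plant (empty anesthesia sections, imprecise
use of "general"), how many identifier entry errors, pre-existing
endophthalmitis histories and true intraoperative complications, and the
follow-up retention schedule. All category counts are planted exactly —
the generator assigns them rather than sampling from proportions — so a
profile describes a cohort, not a distribution over cohorts.

:func:`default_profile` packages the composition of the reference study
cohort of 1418 anterior-chamber liquid biopsies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence, Tuple

__all__ = [
    "ANESTHESIA_LABELS",
    "AKINESIA_LABELS",
    "LOCAL_LABELS",
    "RetentionSchedule",
    "CohortProfile",
    "ProfileError",
    "default_profile",
]

#: Final anesthesia labels a case can carry.
ANESTHESIA_LABELS: Tuple[str, ...] = (
    "topical",
    "peribulbar",
    "subtenon",
    "retrobulbar",
    "general",
)

#: Labels implying pharmacologic ocular muscle akinesia (immobile eye).
AKINESIA_LABELS = frozenset({"retrobulbar", "general"})

#: Local (non-general) anesthesia labels.
LOCAL_LABELS: Tuple[str, ...] = ("topical", "peribulbar", "subtenon", "retrobulbar")


class ProfileError(ValueError):
    """Raised when a profile violates its invariants; names the field."""


@dataclass(frozen=True)
class RetentionSchedule:
    """Planted follow-up structure.

    ``day1`` is the fraction of cases with a documented visit at
    postoperative day 1 exactly; the window fractions are the fraction of
    cases whose *last* visit is at or beyond 7, 30 and 90 days. The
    cohort's median last-visit offset is shaped toward ``median_days``
    and the maximum toward ``max_days`` when the counts permit.
    """

    day1: float = 1408 / 1418
    week1: float = 1377 / 1418
    month1: float = 1256 / 1418
    month3: float = 978 / 1418
    median_days: int = 223
    max_days: int = 2003


# Primary surgical indications with exact case counts (sums to 1418).
_DEFAULT_DIAGNOSIS_MIX: Tuple[Tuple[str, int], ...] = (
    ("cataract", 711),
    ("cataract, glaucoma", 207),
    ("glaucoma", 147),
    ("diabetic cataract", 53),
    ("cataract, pseudoexfoliation", 11),
    ("cataract, glaucoma, pseudoexfoliation", 9),
    ("diabetic cataract, glaucoma", 9),
    ("glaucoma, pseudoexfoliation", 6),
    ("cataract, retinitis pigmentosa", 4),
    ("cataract, proliferative diabetic retinopathy", 3),
    ("trauma", 3),
    ("uveitis, glaucoma", 3),
    ("cataract, corneal edema", 2),
    ("cataract, age-related macular degeneration", 2),
    ("retained lens fragments", 2),
    ("anterior segment, other", 16),
    ("corneal edema", 38),
    ("fuchs endothelial dystrophy", 21),
    ("failed corneal transplant", 15),
    ("corneal opacity", 7),
    ("cornea, other", 8),
    ("retinal detachment", 24),
    ("epiretinal membrane", 19),
    ("proliferative diabetic retinopathy", 11),
    ("vitreous hemorrhage", 9),
    ("macular hole", 8),
    ("endophthalmitis", 6),
    ("retinal detachment, vitreous hemorrhage", 4),
    ("vitreous hemorrhage, proliferative diabetic retinopathy", 4),
    ("retinitis pigmentosa", 3),
    ("uveitis", 3),
    ("neovascular inflammatory vitreoretinopathy", 3),
    ("macular hole, epiretinal membrane", 2),
    ("usher syndrome", 1),
    ("retina, other", 22),
    ("uveal melanoma", 20),
    ("vascular lesion", 1),
    ("tumor, other", 1),
)


@dataclass
class CohortProfile:
    """Exact composition of a synthetic liquid-biopsy cohort."""

    n_cases: int
    n_patients: int
    n_surgeons: int
    diagnosis_mix: Tuple[Tuple[str, int], ...]
    anesthesia_mix: Mapping[str, int]
    technique_needle_fraction: float
    n_no_hit_anesthesia: int
    n_general_term_total: int
    n_general_misuse: int
    n_preexisting_endophthalmitis: int
    n_true_complications: int
    n_identifier_mismatches: int
    followup: RetentionSchedule = field(default_factory=RetentionSchedule)
    seed: int = 0

    def validate(self) -> None:
        """Check every profile invariant; raise :class:`ProfileError` naming the field."""
        count_fields = (
            "n_cases",
            "n_patients",
            "n_surgeons",
            "n_no_hit_anesthesia",
            "n_general_term_total",
            "n_general_misuse",
            "n_preexisting_endophthalmitis",
            "n_true_complications",
            "n_identifier_mismatches",
        )
        for name in count_fields:
            if int(getattr(self, name)) < 0:
                raise ProfileError(f"{name} must be >= 0")
        for label, count in self.diagnosis_mix:
            if count < 0:
                raise ProfileError(f"diagnosis_mix count for {label!r} must be >= 0")
        if sum(c for _, c in self.diagnosis_mix) != self.n_cases:
            raise ProfileError("diagnosis_mix counts must sum to n_cases")
        unknown = set(self.anesthesia_mix) - set(ANESTHESIA_LABELS)
        if unknown:
            raise ProfileError(f"anesthesia_mix has unknown labels {sorted(unknown)}")
        if any(c < 0 for c in self.anesthesia_mix.values()):
            raise ProfileError("anesthesia_mix counts must be >= 0")
        if sum(self.anesthesia_mix.values()) != self.n_cases:
            raise ProfileError("anesthesia_mix counts must sum to n_cases")
        if self.n_general_misuse > self.n_general_term_total:
            raise ProfileError("n_general_misuse must be <= n_general_term_total")
        n_general_true = self.anesthesia_mix.get("general", 0)
        if self.n_general_term_total != n_general_true + self.n_general_misuse:
            raise ProfileError(
                "n_general_term_total must equal anesthesia_mix['general'] + n_general_misuse"
            )
        if self.n_no_hit_anesthesia + self.n_general_term_total > self.n_cases:
            raise ProfileError(
                "n_no_hit_anesthesia + n_general_term_total must be <= n_cases"
            )
        n_local = sum(self.anesthesia_mix.get(l, 0) for l in LOCAL_LABELS)
        if self.n_general_misuse > n_local:
            raise ProfileError("n_general_misuse exceeds the number of local-label cases")
        if self.n_no_hit_anesthesia > self.n_cases - self.n_general_term_total:
            raise ProfileError("n_no_hit_anesthesia exceeds cases without 'general' text")
        if not 0.0 <= self.technique_needle_fraction <= 1.0:
            raise ProfileError("technique_needle_fraction must be in [0, 1]")
        if self.n_cases > 0:
            if not 0 < self.n_patients <= self.n_cases:
                raise ProfileError("n_patients must be in [1, n_cases]")
            if self.n_cases - self.n_patients > self.n_patients:
                raise ProfileError(
                    "n_patients too small: at most one repeat case per patient"
                )
            if self.n_surgeons < 1:
                raise ProfileError("n_surgeons must be >= 1 for a non-empty cohort")
        elif self.n_patients != 0:
            raise ProfileError("n_patients must be 0 when n_cases is 0")
        for name in ("n_preexisting_endophthalmitis", "n_true_complications",
                     "n_identifier_mismatches"):
            if getattr(self, name) > self.n_cases:
                raise ProfileError(f"{name} must be <= n_cases")
        s = self.followup
        fracs = (s.day1, s.week1, s.month1, s.month3)
        if any(not 0.0 <= f <= 1.0 for f in fracs):
            raise ProfileError("followup retention fractions must be in [0, 1]")
        if not (s.day1 >= s.week1 >= s.month1 >= s.month3):
            raise ProfileError(
                "followup retention fractions must be non-increasing with window length"
            )
        if s.median_days < 0 or s.max_days < s.median_days:
            raise ProfileError("followup median_days/max_days inconsistent")

    def with_seed(self, seed: int) -> "CohortProfile":
        return replace(self, seed=int(seed))


def default_profile(seed: int = 0) -> CohortProfile:
    """Profile replicating the reference cohort of 1418 liquid biopsies.

    Composition: 1418 cases on 1154 patients by 17 surgeons; anesthesia
    topical 1021, peribulbar 125, subtenon 61, retrobulbar 147, general
    64 (211 akinesia cases); 65.7% needle technique; 50 anesthesia
    no-hit sections; 104 sections containing "general" of which 40 are
    imprecise usage over local anesthesia with intravenous sedation; 14
    pre-existing endophthalmitis histories; exactly one true
    intraoperative complication (a Descemet membrane tear); 14 manifest
    identifier entry errors; retention 1408/1377/1256/978 at day 1 /
    1 week / 1 month / 3 months with median last visit 223 days
    (range 0-2003).
    """
    return CohortProfile(
        n_cases=1418,
        n_patients=1154,
        n_surgeons=17,
        diagnosis_mix=_DEFAULT_DIAGNOSIS_MIX,
        anesthesia_mix={
            "topical": 1021,
            "peribulbar": 125,
            "subtenon": 61,
            "retrobulbar": 147,
            "general": 64,
        },
        technique_needle_fraction=0.657,
        n_no_hit_anesthesia=50,
        n_general_term_total=104,
        n_general_misuse=40,
        n_preexisting_endophthalmitis=14,
        n_true_complications=1,
        n_identifier_mismatches=14,
        followup=RetentionSchedule(),
        seed=int(seed),
    )
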