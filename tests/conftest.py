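import numpy as np
import pytest

from actap import CohortProfile, RetentionSchedule, default_profile
from actap.pipeline import PipelineConfig, run_pipeline


def make_small_profile(
    seed: int = 0,
    n_cases: int = 120,
    n_true_complications: int = 1,
    n_identifier_mismatches: int = 3,
    n_preexisting_endophthalmitis: int = 3,
    n_no_hit_anesthesia: int = 5,
    n_general_misuse: int = 4,
) -> CohortProfile:
    """A scaled-down cohort with the same planted phenomena as the default."""
    n = n_cases
    retro, peri, sub, gen = 12, 10, 5, 6
    diag_endo = min(2, n)
    return CohortProfile(
        n_cases=n,
        n_patients=n - n // 10,
        n_surgeons=5,
        diagnosis_mix=(("cataract", n - diag_endo), ("endophthalmitis", diag_endo)),
        anesthesia_mix={
            "topical": n - (retro + peri + sub + gen),
            "peribulbar": peri,
            "subtenon": sub,
            "retrobulbar": retro,
            "general": gen,
        },
        technique_needle_fraction=0.65,
        n_no_hit_anesthesia=n_no_hit_anesthesia,
        n_general_term_total=gen + n_general_misuse,
        n_general_misuse=n_general_misuse,
        n_preexisting_endophthalmitis=n_preexisting_endophthalmitis,
        n_true_complications=n_true_complications,
        n_identifier_mismatches=n_identifier_mismatches,
        followup=RetentionSchedule(),
        seed=seed,
    )


def random_profile(rng: np.random.Generator) -> CohortProfile:
    """A random valid profile for invariant/property sweeps (small n)."""
    n = int(rng.integers(20, 81))
    gen = int(rng.integers(0, n // 10 + 1))
    retro = int(rng.integers(0, n // 8 + 1))
    peri = int(rng.integers(0, n // 8 + 1))
    sub = int(rng.integers(0, n // 10 + 1))
    top = n - gen - retro - peri - sub
    n_local = top + peri + sub + retro
    misuse = int(rng.integers(0, min(3, n_local) + 1))
    no_hit = int(rng.integers(0, min(5, n - gen - misuse) + 1))
    endo_diag = int(rng.integers(0, min(2, n) + 1))
    fracs = np.sort(rng.uniform(0, 1, size=4))[::-1]
    return CohortProfile(
        n_cases=n,
        n_patients=n - int(rng.integers(0, n // 4 + 1)),
        n_surgeons=int(rng.integers(1, 6)),
        diagnosis_mix=(("cataract", n - endo_diag), ("endophthalmitis", endo_diag)),
        anesthesia_mix={
            "topical": top, "peribulbar": peri, "subtenon": sub,
            "retrobulbar": retro, "general": gen,
        },
        technique_needle_fraction=float(rng.uniform(0, 1)),
        n_no_hit_anesthesia=no_hit,
        n_general_term_total=gen + misuse,
        n_general_misuse=misuse,
        n_preexisting_endophthalmitis=int(rng.integers(0, min(4, n) + 1)),
        n_true_complications=int(rng.integers(0, 3)),
        n_identifier_mismatches=int(rng.integers(0, min(4, n) + 1)),
        followup=RetentionSchedule(
            day1=float(fracs[0]), week1=float(fracs[1]),
            month1=float(fracs[2]), month3=float(fracs[3]),
        ),
        seed=int(rng.integers(0, 2**31 - 1)),
    )


@pytest.fixture(scope="session")
def default_result():
    """Full pipeline run on the packaged 1418-case cohort (seed 1)."""
    config = PipelineConfig(
        out_dir="unused", seed=1, profile=default_profile(1),
        write_outputs=False,
    )
    return run_pipeline(config)


@pytest.fixture(scope="session")
def default_corpus(default_result):
    return default_result.corpus


@pytest.fixture()
def small_profile():
    return make_small_profile(seed=3)
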