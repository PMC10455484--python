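import pytest
from hypothesis import HealthCheck, settings

from cypome.config import DEFAULT_RULES
from cypome.nomenclature import assign_p450s
from cypome.synthetic import SyntheticSpec, generate_cohort

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def rules():
    return DEFAULT_RULES


@pytest.fixture(scope="session")
def cohort():
    """Small four-species cohort with members in all identity bands plus
    fragments and both decoy kinds."""
    spec = SyntheticSpec(
        seed=11,
        n_species=4,
        n_founder_families=5,
        members_per_species=12,
        false_positives_per_species={"SYN01": 1},
        no_hits_per_species={"SYN01": 1, "SYN02": 1},
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def cohort_assignments(cohort):
    """Nomenclature assignments for every planted true P450 in the cohort."""
    p450_ids = set(cohort.truth[cohort.truth.category == "P450"].protein_id)
    queries = [
        r for recs in cohort.proteomes.values() for r in recs
        if r.id in p450_ids
    ]
    return assign_p450s(queries, cohort.references)
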