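import pytest

from repclass.preprocessing import downsample_cohort
from repclass.repertoire_io import aggregate_by_cdr3, build_cohort_matrix
from repclass.synthetic_data import (
    ImplantedClone,
    SyntheticSpec,
    default_implants,
    generate_cohort,
)


@pytest.fixture(scope="session")
def tiny_spec():
    """Small, fast cohort with the default (partial-signal) implants."""
    return SyntheticSpec(
        n_case=8,
        n_control=10,
        umis_per_sample=(2_000, 8_000),
        background_pool_size=2_000,
        seed=11,
        implanted_clones=default_implants("TOP_DOWN"),
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_spec):
    return [aggregate_by_cdr3(r) for r in generate_cohort(tiny_spec)]


@pytest.fixture(scope="session")
def tiny_matrix(tiny_cohort):
    ds = downsample_cohort(tiny_cohort, seed=11)
    return build_cohort_matrix(ds.repertoires)


@pytest.fixture(scope="session")
def separable_spec():
    """Cohort with deterministic implants: every case carries all three
    discriminative clones, no control does."""
    implants = tuple(
        ImplantedClone(c.cdr3_aa, c.v_gene, c.j_gene, 1.0, 0.0)
        for c in default_implants("TOP_DOWN")
    )
    return SyntheticSpec(
        n_case=8,
        n_control=10,
        umis_per_sample=(2_000, 8_000),
        background_pool_size=2_000,
        seed=23,
        implanted_clones=implants,
    )


@pytest.fixture(scope="session")
def separable_matrix(separable_spec):
    reps = [aggregate_by_cdr3(r) for r in generate_cohort(separable_spec)]
    ds = downsample_cohort(reps, seed=23)
    return build_cohort_matrix(ds.repertoires)
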