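import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from panelforge.genome import Region
from panelforge.joint_panel import joint_genotype_region
from panelforge.synthetic import (
    CohortSpec,
    observe,
    scaled_x_length,
    simulate_truth,
)


@pytest.fixture(scope="session")
def small_cohort():
    """20 clean diploid samples with a duplicate and a trio on one autosome."""
    spec = CohortSpec(
        n_samples=20,
        contig_plan=(("autosome", 500_000),),
        n_sites=300,
        genotype_error=0.0,
        array_no_call_rate=0.0,
        array_marker_fraction=0.6,
        relative_plan=(("duplicate", 1), ("parent_offspring", 1)),
        seed=101,
    )
    truth = simulate_truth(spec)
    return truth, observe(truth)


@pytest.fixture(scope="session")
def small_cohort_sites(small_cohort):
    truth, records = small_cohort
    contig = truth.contigs[0]
    return truth, joint_genotype_region(records, Region(contig.name, 1, contig.length))


@pytest.fixture(scope="session")
def x_cohort():
    """40 mixed-sex samples on a 1/100-scale X with diploid-behaving XTR."""
    spec = CohortSpec(
        n_samples=40,
        contig_plan=(("chrX", scaled_x_length()),),
        n_sites=400,
        genotype_error=0.0,
        array_marker_fraction=1.0,
        array_no_call_rate=0.0,
        seed=202,
    )
    truth = simulate_truth(spec)
    return truth, observe(truth)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
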