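import numpy as np
import pytest

from urobiome.cohort_io import SampleSheet, TaxonProfileTable, taxon_record
from urobiome.synthetic_cohort import (
    ContaminantSpec,
    SimulationConfig,
    generate_profiles,
    spike_contaminants,
)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_table(relabund, lineages=None, sample_ids=None, **kw):
    """Small profile-table factory for hand-built fixtures."""
    relabund = np.asarray(relabund, dtype=float)
    n, p = relabund.shape
    if lineages is None:
        lineages = [
            f"k__Bacteria|p__P|c__C|o__O|f__F|g__G|s__Species_{j}" for j in range(p)
        ]
    if sample_ids is None:
        sample_ids = [f"S{i}" for i in range(n)]
    return TaxonProfileTable(
        sample_ids=sample_ids,
        taxa=[taxon_record(lin) for lin in lineages],
        relabund=relabund,
        **kw,
    )


@pytest.fixture(scope="session")
def contaminated_cohort():
    """A small spiked cohort shared across decontamination tests."""
    cfg = SimulationConfig(n_study=150, n_taxa=40, plate_capacity=50)
    table, sheet, truth = generate_profiles(cfg, 11)
    spec = ContaminantSpec(n_cohort=6, n_plate_specific=2, pcr_log_sd=0.8)
    return spike_contaminants(table, sheet, truth, spec, 12)


@pytest.fixture(scope="session")
def clustered_cohort():
    """A 5-cluster cohort with clear structure for urotyping tests."""
    cfg = SimulationConfig(n_study=200, n_taxa=50)
    return generate_profiles(cfg, 21)
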