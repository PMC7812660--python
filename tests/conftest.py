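import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from porelist.records import (
    AgeClass, DatasetId, DecayStage, OccurrenceRecord, SubstrateFraction,
    TreeClass,
)
from porelist.synthetic import (
    default_survey_design, ground_truth, sample_species_pool, simulate_survey,
)


@pytest.fixture
def make_record():
    """Factory for minimal valid occurrence records."""

    def _make(species="sp001", dataset=DatasetId.IIc, year=2010, **kw):
        defaults = dict(
            plot_id="plot001", site_type_group="meso_eutrophic",
            tree_class=TreeClass.picea, age_class=AgeClass.other,
            host_taxon="Picea abies",
            substrate_fraction=SubstrateFraction.coarse_fallen,
            decay_raw=DecayStage.III,
        )
        defaults.update(kw)
        return OccurrenceRecord(species_id=species, dataset_id=dataset,
                                year=year, **defaults)

    return _make


@pytest.fixture(scope="session")
def default_sim():
    """One simulated survey at the packaged default effort (seed 0)."""
    pool = sample_species_pool(seed=0)
    records = simulate_survey(pool, default_survey_design(seed=0))
    return pool, ground_truth(pool), records


@pytest.fixture(scope="session")
def sims20():
    """Simulated surveys for seeds 0-19, shared by the recovery tests."""
    out = {}
    for seed in range(20):
        pool = sample_species_pool(seed=seed)
        records = simulate_survey(pool, default_survey_design(seed=seed))
        out[seed] = (pool, ground_truth(pool), records)
    return out
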