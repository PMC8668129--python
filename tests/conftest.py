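import pytest

from igclone import locus_model as lm
from igclone import synthetic_data as sd
from igclone import vdj_detection as vd


@pytest.fixture(scope="session")
def locus() -> lm.LocusDefinition:
    return lm.default_locus()


@pytest.fixture(scope="session")
def mono_sim(locus):
    """Six monoclonal samples at default 30x — shared by detection,
    genotype-impact and conservation tests."""
    config = sd.SimConfig(seed=1, n_samples=6, n_clones=1)
    return sd.simulate_cohort(config, locus)


@pytest.fixture(scope="session")
def mixed_sim(locus):
    """A 30-sample cohort with natural clonality spread (Dirichlet pools,
    1-12 clones) — shared by correlation and strata tests."""
    config = sd.SimConfig(seed=7, n_samples=30, n_clones=(1, 12), dirichlet_alpha=0.35)
    return sd.simulate_cohort(config, locus)


@pytest.fixture(scope="session")
def mixed_profiles(mixed_sim, locus):
    return [
        vd.profile_sample(mixed_sim.sample_pairs(s), locus, s)
        for s in mixed_sim.sample_ids
    ]
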