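import pytest

import brainmosaic as bm


@pytest.fixture(scope="session")
def table1():
    return bm.load_table1()


@pytest.fixture(scope="session")
def default_cohort():
    """The reference study-condition cohort: 400 samples x 5000 sites,
    depth ~ N(51.9, 12.9) truncated at 1, het VAF 0.47."""
    return bm.simulate_cohort(bm.SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def default_discovery(default_cohort):
    c = default_cohort
    survivors, audit, mask = bm.run_discovery(
        c.sites, c.depth, c.alt_count, c.sample_ids,
        blacklist=c.blacklist, cnv=c.cnv, popfreq=c.popfreq, seed=1,
    )
    return survivors, audit, mask
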