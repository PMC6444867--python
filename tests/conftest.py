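import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import plasmacna as pc
from plasmacna.gcnorm import raw_to_percent

settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy_build():
    """Small 2-chromosome build for fast grid/counting tests."""
    return pc.toy_genome(2, 5_000_000)


@pytest.fixture(scope="session")
def sim_cohort():
    """One default-condition synthetic cohort, shared across tests.

    14 controls plus 4 patients at tumor fractions 0, 0.1, 0.2, 0.3 on the
    default toy genome.
    """
    cfg = pc.SimulationConfig(seed=7, n_patients=4,
                              tumor_fractions=(0.0, 0.1, 0.2, 0.3))
    controls, patients, gc, binset, truth = pc.simulate_bin_counts(cfg)
    return cfg, controls, patients, gc, binset, truth


@pytest.fixture(scope="session")
def sim_percent(sim_cohort):
    """The same cohort pushed through GC correction and normalization."""
    cfg, controls, patients, gc, binset, truth = sim_cohort
    ctrl_pct = [raw_to_percent(c, gc, binset) for c in controls]
    pat_pct = [raw_to_percent(p, gc, binset) for p in patients]
    return ctrl_pct, pat_pct, binset, truth
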