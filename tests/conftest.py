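import numpy as np
import pytest

from glandevo.synthetic import (
    CloneSpec,
    CnlohEventSpec,
    SimulationConfig,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def small_cohort():
    """Two-subject cohort with one planted CN-LOH, reused across tests."""
    event = CnlohEventSpec(
        chrom="chr3", start=1, end=20_000_000, true_age=10.0, rho=1.0
    )
    specs = {
        "S01": (
            CloneSpec(
                name="c1", n_glands=5, expansion_age=20.0,
                grid_cells=("0,0", "0,1", "1,0", "1,1", "0,2"),
                cnloh_events=(event,),
            ),
        ),
        "S02": (
            CloneSpec(name="c1", n_glands=4, expansion_age=25.0),
        ),
    }
    # whole-genome-like: the full synthetic genome (100 Mbp) is callable,
    # so the CN-LOH region holds enough public SNVs to be timed
    config = SimulationConfig(
        n_subjects=2, ages=(40.0, 50.0), clone_specs=specs,
        depth_mean=100.0, callable_mb=100.0, seed=11,
    )
    return simulate_cohort(config)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
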