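import numpy as np
import pytest

from anlagen import SimConfig, FamilySpec, simulate_timecourse
from anlagen.simulate import default_families


def two_family_config(**overrides):
    """Small two-family scenario for fast generative-recovery tests."""
    fams = [
        FamilySpec("Alpha", [f"Amk{i:02d}" for i in range(20)], marker_fold=5.0),
        FamilySpec("Beta", [f"Bmk{i:02d}" for i in range(20)], marker_fold=5.0),
    ]
    kwargs = dict(
        n_genes=400,
        families=fams,
        timepoints=[0],
        replicates_per_timepoint=2,
        cells_per_replicate=200,
        composition={0: {"Alpha": 0.5, "Beta": 0.5}},
        seed=11,
    )
    kwargs.update(overrides)
    return SimConfig(**kwargs)


@pytest.fixture(scope="session")
def small_timecourse():
    """Default 7-family design scaled down: 2 days x 2 replicates x 250 cells."""
    config = SimConfig(
        n_genes=600,
        timepoints=[0, 7],
        cells_per_replicate=250,
        seed=5,
    )
    matrices, truth = simulate_timecourse(config)
    return config, matrices, truth


@pytest.fixture(scope="session")
def noise_free_result(noise_free_timecourse):
    """One consolidation run of the noise-free design, shared across tests."""
    from anlagen import consolidate_timecourse

    _, matrices, truth = noise_free_timecourse
    return consolidate_timecourse(matrices, seed=0), truth


@pytest.fixture(scope="session")
def noise_free_timecourse():
    """Deterministic (expected-count) version of the design for exactness tests."""
    config = SimConfig(
        n_genes=600,
        cells_per_replicate=200,
        noise_free=True,
        batch_effect_sd=0.0,
        seed=9,
    )
    matrices, truth = simulate_timecourse(config)
    return config, matrices, truth
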