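"""Shared fixtures: small networks for unit tests, study-scale nets for the
acceptance suite (session-scoped so training happens once)."""

import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import hopaux as hx
import hopaux.experiments as ex

settings.register_profile(
    "suite", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("suite")

# Replication settings for the reduced-scale trend checks: 5 independent seed
# streams, each running 5 lesion/noise realisations over all 20 memories.
TREND_SEEDS = 5
TREND_REPEATS = 5
TREND_MASTER_SEED = 1234


@pytest.fixture(scope="session")
def small_memories() -> hx.MemorySet:
    """Five near-orthogonal memories over 200 neurons."""
    return hx.generate_synthetic_patterns(5, 200, max_abs_overlap=0.3, seed=3)


@pytest.fixture(scope="session")
def small_net(small_memories):
    """Trained coupled network at toy scale (200 original, 50 auxiliary)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        net, augmented = hx.train_augmented_network(
            small_memories, n_aux=50, density_C=0.1, density_B=0.3, seed=4)
    return net, augmented


@pytest.fixture(scope="session")
def study_config() -> ex.SweepConfig:
    """Full-size study conditions: 1000 neurons, 20 of 30 memories, C at 5%."""
    return ex.SweepConfig(memory_sets=("optimal", "nonoptimal"),
                          master_seed=TREND_MASTER_SEED)


@pytest.fixture(scope="session")
def study_sets(study_config):
    """Optimal and nonoptimal 20-memory sets over 1000 neurons."""
    return ex.build_memory_sets(study_config)


@pytest.fixture(scope="session")
def study_nets(study_config, study_sets):
    """Calibrated coupled networks keyed by (memory set kind, n_aux).

    Each value is ``(base_network, augmented_memories)``; the feedback block
    B is re-masked per density by the tests that need it.
    """
    nets = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for kind in ("optimal", "nonoptimal"):
            for n_aux in (200, 400):
                nets[(kind, n_aux)] = ex.train_for_sweep(
                    study_config, study_sets[kind], kind, n_aux)
    return nets


@pytest.fixture(scope="session")
def net_with_density(study_config, study_sets, study_nets):
    """Factory: stage-5 network for a given set kind, auxiliary size and B density."""
    def _make(kind: str, n_aux: int, density_B: float) -> hx.BlockConnectivity:
        base, augmented = study_nets[(kind, n_aux)]
        return ex._with_density_B(study_config, base, study_sets[kind],
                                  augmented.auxiliaries, kind, n_aux, density_B)
    return _make
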