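"""Shared fixtures: desk-scale synthetic cohorts and split plans.

The heavier cohorts are session-scoped so the signal-recovery and
null-specificity suites reuse the same generated data.
"""

import numpy as np
import pytest

from ssmbench import CohortConfig, generate_cohort, make_splits


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny cohort for structural / determinism checks."""
    return generate_cohort(CohortConfig(
        n_subjects=60, n_nodes=30, n_voxels=200, n_rois=20, seed=11,
    ))


@pytest.fixture(scope="session")
def signal_cohort():
    """240-subject cohort with half the outcome variance carried by the brain factor."""
    return generate_cohort(CohortConfig(
        n_subjects=240, n_nodes=64, n_voxels=800, n_rois=68,
        snr_per_domain=(0.5, 0.5, 0.5, 0.5), seed=3,
    ))


@pytest.fixture(scope="session")
def null_cohort():
    """Same design with zero brain signal: outcomes are demographics plus noise."""
    return generate_cohort(CohortConfig(
        n_subjects=240, n_nodes=64, n_voxels=800, n_rois=68,
        snr_per_domain=(0.0, 0.0, 0.0, 0.0), seed=5,
    ))


@pytest.fixture(scope="session")
def plan100():
    """100 Monte-Carlo 80/20 splits of 240 subjects, shared across suites."""
    return make_splits(np.arange(240), n_iterations=100, seed=1)
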