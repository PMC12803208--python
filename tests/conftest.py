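"""Shared fixtures: small seeded synthetic cohorts run through the pipeline.

Session-scoped so the heavier cohorts are generated once per run.
"""

from __future__ import annotations

import numpy as np
import pytest

from framefp.cohort import CohortConfig
from framefp.experiments import pipeline_eigenseries
from framefp.fingerprint import run_identification

# A cohort whose subject component dominates the mixture (subject variance
# 10x the noise floor), so identity is recoverable from single frames.
STRONG_WEIGHTS = dict(
    group_weight=0.5,
    subject_weight=3.0,
    task_weight=0.0,
    subject_task_weight=0.0,
    session_noise_weight=0.3,
    latent_rank=5,
)

# No subject, task, or subject-by-task structure: scans are exchangeable
# across subjects and identification can only succeed at chance.
NULL_WEIGHTS = dict(
    group_weight=1.0,
    subject_weight=0.0,
    task_weight=0.0,
    subject_task_weight=0.0,
    session_noise_weight=1.0,
)


@pytest.fixture(scope="session")
def strong_cohort():
    """10 subjects x 4 sessions with a dominant subject component."""
    cfg = CohortConfig(
        n_subjects=10,
        n_sessions=4,
        n_nodes=50,
        n_volumes=150,
        seed=11,
        **STRONG_WEIGHTS,
    )
    series, flags, tsnr = pipeline_eigenseries(cfg)
    return cfg, series


@pytest.fixture(scope="session")
def strong_report(strong_cohort):
    _, series = strong_cohort
    return run_identification(series)


@pytest.fixture(scope="session")
def null_cohort():
    """6 subjects x 2 sessions with no identity signal by construction."""
    cfg = CohortConfig(
        n_subjects=6,
        n_sessions=2,
        n_nodes=30,
        n_volumes=120,
        seed=0,
        **NULL_WEIGHTS,
    )
    series, _, _ = pipeline_eigenseries(cfg)
    return cfg, series


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
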