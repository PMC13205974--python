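"""Shared fixtures: small synthetic series for unit tests and the full
default-cohort pipeline (computed once per session) for acceptance checks."""

from __future__ import annotations

import numpy as np
import pytest

from patellakin.pipeline import run_pipeline
from patellakin.registration import OptimizerConfig
from patellakin.synthetic import (
    CohortConfig,
    default_templates,
    make_patella_cloud,
    render_frame_series,
    sample_phenotype_trajectory,
)


@pytest.fixture(scope="session")
def patella_cloud():
    return make_patella_cloud(44.99, 40.62, 300, seed=11)


@pytest.fixture(scope="session")
def short_series(patella_cloud):
    """A noiseless 10-frame intermediate-phenotype series with ground truth."""
    template = default_templates()[1]
    poses, dof = sample_phenotype_trajectory(template, 10, seed=21)
    return render_frame_series(
        patella_cloud, poses, 0.0, "right", seed=31, subject_id="short", truth_dof=dof
    )


@pytest.fixture(scope="session")
def noisy_series(patella_cloud):
    template = default_templates()[1]
    poses, dof = sample_phenotype_trajectory(template, 10, seed=22)
    return render_frame_series(
        patella_cloud, poses, 0.3, "right", seed=32, subject_id="noisy", truth_dof=dof
    )


@pytest.fixture(scope="session")
def default_pipeline():
    """The full study pipeline on the fixed default 64-knee cohort.

    Runs pose reconstruction at 300 points per frame; shared session-wide
    because it is by far the most expensive fixture (~half a minute).
    """
    return run_pipeline(
        cohort_config=CohortConfig(n_points=300, seed=0),
        optimizer_config=OptimizerConfig(),
        seed=0,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
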