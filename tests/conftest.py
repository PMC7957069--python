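"""Shared fixtures: synthetic cohorts and one full training pipeline run.

The full pipeline at the default cohort scale (n = 400) takes a couple of
minutes, so it runs once per session and is shared by the pipeline and
acceptance tests.
"""

import numpy as np
import pytest

from tmescore.config import RunConfig
from tmescore.pipeline import run_pipeline
from tmescore.simulate import generate_signature_matrix, simulate_cohort


@pytest.fixture(scope="session")
def signature():
    return generate_signature_matrix(seed=1)


@pytest.fixture(scope="session")
def small_cohort(signature):
    """120-sample cohort for module-level checks."""
    return simulate_cohort(n_samples=120, signature=signature, seed=7)


@pytest.fixture(scope="session")
def pipeline_result(tmp_path_factory):
    """One full default-scale training run (n = 400, planted HR 2.5)."""
    outdir = tmp_path_factory.mktemp("pipeline") / "run"
    config = RunConfig(seed=1, outdir=str(outdir))
    return run_pipeline(config)


@pytest.fixture(scope="session")
def validation_cohort(pipeline_result):
    """Independently seeded cohort from the same generative process
    (same signature and gene population) as the training run."""
    return simulate_cohort(n_samples=400, signature=pipeline_result.signature,
                           seed=20210301)


def subtype_accuracy(result):
    """Agreement between pipeline subtype labels and planted truth."""
    truth = result.truth.true_subtype
    pred = result.score_table["subtype"].map(
        {"TMEscore-high": "high", "TMEscore-low": "low"}
    )
    return float((pred == truth).mean())
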