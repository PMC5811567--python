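"""Shared fixtures: one synthetic study and pipeline run per session."""

from __future__ import annotations

import pytest
from hypothesis import settings

from bulbmir.evaluate import score_against_truth
from bulbmir.pipeline import PipelineConfig, run_study
from bulbmir.simulate import simulate_study

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

ROUND_TRIP_SEED = 1


@pytest.fixture(scope="session")
def study():
    """The default synthetic study at the fixed round-trip seed."""
    return simulate_study(seed=ROUND_TRIP_SEED)


@pytest.fixture(scope="session")
def study_result(study):
    config = PipelineConfig(adapter=study.adapter)
    return run_study(study.libraries, study.transcripts, study.known_records,
                     study.annotation, study.degradome_tags, config)


@pytest.fixture(scope="session")
def recovery(study, study_result):
    return score_against_truth(study, study_result)
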