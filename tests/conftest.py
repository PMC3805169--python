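"""Shared fixtures: the default grammar, its enumeration, and one full-scale
simulation run reused by the slower directional tests."""

import numpy as np
import pytest
from hypothesis import settings

from mandarin_rc.experiment import ExperimentConfig, run_experiment
from mandarin_rc.gpe import TargetOracle
from mandarin_rc.grammar import GrammarSpec, enumerate_templates, generate_corpus

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def grammar():
    return GrammarSpec()


@pytest.fixture(scope="session")
def templates(grammar):
    return enumerate_templates(grammar)


@pytest.fixture(scope="session")
def oracle(grammar, templates):
    return TargetOracle(
        templates, enumerate_templates(grammar.structural_variant())
    )


@pytest.fixture(scope="session")
def small_corpus(grammar, templates):
    return generate_corpus(grammar, 500, seed=11, templates=templates)


@pytest.fixture(scope="session")
def full_results():
    """The full study-scale run: 10 networks x 10,000 sentences x 1 epoch,
    160 novel test items, default configuration."""
    config = ExperimentConfig(master_seed=1)
    return run_experiment(config)
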