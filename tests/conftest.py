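"""Shared fixtures: motif models, a default synthetic genome, pipeline runs."""

from __future__ import annotations

import numpy as np
import pytest

from nlrscan.motifs import load_motifs
from nlrscan.pipeline import PipelineConfig, run_pipeline
from nlrscan.scan import BACKGROUND, build_scoring_model
from nlrscan.simulate import (
    SimulationConfig,
    simulate_genome,
    simulate_training_sets,
)

DEFAULT_SEED = 1


@pytest.fixture(scope="session")
def motifs():
    return load_motifs()


@pytest.fixture(scope="session")
def models(motifs):
    return {m: build_scoring_model(d) for m, d in motifs.items()}


def random_protein(rng: np.random.Generator, length: int) -> str:
    from nlrscan.motifs import AMINO_ACIDS
    return "".join(rng.choice(list(AMINO_ACIDS), size=length, p=BACKGROUND))


@pytest.fixture(scope="session")
def sim():
    return simulate_genome(SimulationConfig(seed=DEFAULT_SEED))


@pytest.fixture(scope="session")
def training_sets():
    return simulate_training_sets(SimulationConfig(seed=DEFAULT_SEED))


@pytest.fixture(scope="session")
def pipeline_result(sim, training_sets):
    pos, neg = training_sets
    return run_pipeline(sim.bundle, pos, neg,
                        PipelineConfig(seed=DEFAULT_SEED))


@pytest.fixture(scope="session")
def pipeline_result_no_extension(sim, training_sets):
    pos, neg = training_sets
    return run_pipeline(sim.bundle, pos, neg,
                        PipelineConfig(seed=DEFAULT_SEED,
                                       skip_extension=True))
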