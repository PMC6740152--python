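"""Shared fixtures: small and full-scale simulations with ground truth."""

from __future__ import annotations

import numpy as np
import pytest

from sidescan import PipelineConfig, ScoringScheme
from sidescan.pipeline import survey_pair
from sidescan.simulate import SimulationConfig, plant_copies


@pytest.fixture(scope="session")
def scheme() -> ScoringScheme:
    return ScoringScheme()


@pytest.fixture(scope="session")
def small_sim():
    """200 kb genome, 15 LINE + 30 SIDE copies at burst d=0.05."""
    cfg = SimulationConfig(genome_len=200_000, n_line=15, n_side=30, rng_seed=1)
    genome, truth, master_line, master_side = plant_copies(cfg)
    return cfg, genome, truth, master_line, master_side


@pytest.fixture(scope="session")
def default_sim():
    """The full default scenario: 2 Mb, 150 LINE + 300 SIDE, burst d=0.05."""
    cfg = SimulationConfig(rng_seed=1)
    genome, truth, master_line, master_side = plant_copies(cfg)
    return cfg, genome, truth, master_line, master_side


@pytest.fixture(scope="session")
def default_survey(default_sim):
    """Full recovery pipeline run on the default simulation."""
    _, genome, truth, master_line, master_side = default_sim
    surveys = survey_pair(master_line, master_side, [genome], PipelineConfig())
    return surveys, truth


def interval_matches(truth_iv, copy_iv, min_frac: float = 0.5) -> bool:
    ov = min(truth_iv.end, copy_iv.end) - max(truth_iv.start, copy_iv.start)
    return ov > min_frac * min(len(truth_iv), len(copy_iv))


def recall_against_truth(copies, truth, family: str) -> float:
    relevant = [t for t in truth if t.family == family]
    found = 0
    for t in relevant:
        if any(
            c.genome_iv.seq_id == t.genome_iv.seq_id
            and interval_matches(t.genome_iv, c.genome_iv)
            for c in copies
        ):
            found += 1
    return found / len(relevant) if relevant else float("nan")
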