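"""Shared fixtures: small simulated datasets and schedule factories."""

from __future__ import annotations

import numpy as np
import pytest

from fairmirror.config import SimConfig, default_signal_spec
from fairmirror.simulate import (
    Block,
    BlockSchedule,
    ConfederateAssignment,
    make_block_schedule,
    make_counterbalance,
)

#: Desk-scale conditions used across the MVPA/permutation suites.
TEST_DIMS = (12, 12, 8)
TEST_BLOCKS_PER_RUN = 16


@pytest.fixture(scope="session")
def assignment() -> ConfederateAssignment:
    return ConfederateAssignment(
        subject_id="sub-01",
        identity_to_role={"A": "fair", "B": "unfair"},
        identity_to_color={"A": "blue", "B": "orange"},
    )


@pytest.fixture(scope="session")
def default_config() -> SimConfig:
    return SimConfig(error_rate=0.0)


@pytest.fixture(scope="session")
def default_schedule(default_config, assignment) -> BlockSchedule:
    return make_block_schedule(default_config, assignment, seed=42)


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(
        n_subjects=15,
        volume_dims=TEST_DIMS,
        blocks_per_run=TEST_BLOCKS_PER_RUN,
        error_rate=0.0,
    )


def make_manual_schedule(onsets_by_cell: dict, assignment: ConfederateAssignment, run: int = 0):
    """Schedule with blocks of given cells at explicit onsets (for SOA tests)."""
    blocks = []
    for (modality, stim_type, role), onsets in onsets_by_cell.items():
        identity = assignment.role_to_identity[role]
        color = assignment.identity_to_color[identity]
        for onset in onsets:
            blocks.append(
                Block(
                    run=run,
                    onset_s=float(onset),
                    modality=modality,
                    stim_type=stim_type,
                    role=role,
                    identity=identity,
                    color=color,
                )
            )
    blocks.sort(key=lambda b: b.onset_s)
    return BlockSchedule(subject_id=assignment.subject_id, blocks=tuple(blocks), assignment=assignment)


def planted_example_set(
    n_subjects: int = 15,
    dims: tuple[int, int, int] = TEST_DIMS,
    role_amp: float = 2.0,
    conf_amp: float = 0.5,
    noise_sd: float = 0.5,
    seed: int = 0,
    chunked: bool = False,
):
    """Simulated role ExampleSet with a strong planted pattern by default."""
    from fairmirror.pipeline import simulate_role_examples

    sim = SimConfig(
        n_subjects=n_subjects,
        volume_dims=dims,
        blocks_per_run=TEST_BLOCKS_PER_RUN,
        error_rate=0.0,
    )
    spec = default_signal_spec(
        sim,
        role_pattern_amplitude=role_amp,
        confound_pattern_amplitude=conf_amp,
        noise_sd=noise_sd,
    )
    examples = simulate_role_examples(sim, spec, seed=seed, chunked=chunked)
    return examples, spec, sim
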