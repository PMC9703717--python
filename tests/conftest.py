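"""Shared fixtures: the default synthetic study, built once per session."""

from __future__ import annotations

import pytest

from cewhiten import bsjcall
from cewhiten.synthio import SimulationConfig, generate_dataset


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def dataset(default_config):
    return generate_dataset(default_config)


@pytest.fixture(scope="session")
def genome_index(dataset):
    return bsjcall.build_index(dataset.genome)


@pytest.fixture(scope="session")
def credible_circs(dataset, genome_index):
    """Dual-evidence credible circRNA calls on the default dataset."""
    cfg = dataset.config
    per_sample = {
        s: bsjcall.detect_sample(dataset.read_sets["wholetx"][s], genome_index, s)
        for s in cfg.sample_ids
    }
    wholetx = bsjcall.combine_samples(per_sample, min_unique=2)
    circseq = bsjcall.combine_samples(
        {"pool": bsjcall.detect_sample(dataset.read_sets["circseq"], genome_index, "pool")},
        min_unique=2,
    )
    return bsjcall.merge_dual_evidence(circseq, wholetx)
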