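"""Shared fixtures: the packaged catalog and one fully simulated scenario."""
from __future__ import annotations

from dataclasses import dataclass

import pytest

from tymap.catalog import TyCatalog, load_sk1_catalog
from tymap.detect import DetectionResult, LibraryStats, detect_insertions
from tymap.simulate import (GroundTruth, SimConfig, make_exemplars,
                            make_reference_genome, plant_insertions,
                            simulate_mate_pairs)


@pytest.fixture(scope="session")
def sk1_catalog() -> TyCatalog:
    return load_sk1_catalog()


@dataclass
class SimBundle:
    config: SimConfig
    genome: dict
    annotation: object
    exemplars: list
    sample: dict
    truth: GroundTruth
    pairs: list
    library: LibraryStats


@pytest.fixture(scope="session")
def sim_bundle() -> SimBundle:
    """One deterministic error-free scenario at the default study geometry."""
    config = SimConfig(seed=7)
    genome, annotation = make_reference_genome(config)
    exemplars = make_exemplars(config)
    sample, truth = plant_insertions(genome, annotation, exemplars, config)
    pairs = simulate_mate_pairs(sample, config)
    return SimBundle(
        config=config, genome=genome, annotation=annotation,
        exemplars=exemplars, sample=sample, truth=truth, pairs=pairs,
        library=LibraryStats(insert_mean=config.insert_mean,
                             insert_sd=config.insert_sd,
                             read_len=config.read_len))


@pytest.fixture(scope="session")
def detection(sim_bundle: SimBundle) -> DetectionResult:
    return detect_insertions(
        sim_bundle.pairs, sim_bundle.genome, sim_bundle.exemplars,
        sim_bundle.library)
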