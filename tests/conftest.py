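"""Shared fixtures: a small synthetic study run once per session."""

from __future__ import annotations

from dataclasses import dataclass

import pytest

from nutrimir import annotate, mapper, preprocess, synthio


@dataclass
class StudyRun:
    """A fully processed synthetic two-condition experiment."""

    config: synthio.SimulationConfig
    chroms: dict
    annotations: list
    transcripts: dict
    truth: synthio.SyntheticTruth
    table: preprocess.ReadTagTable
    mapped: list
    mapped_table: preprocess.ReadTagTable
    classes: dict
    known_matures: set


MINI_CONFIG = synthio.SimulationConfig(
    n_chromosomes=2,
    chromosome_length=15_000,
    n_novel_mirnas=3,
    n_known_mirnas=2,
    n_structural=4,
    n_decoys=3,
    n_transcripts=5,
    depth=10_000,
    dispersion=0.1,
    seed=11,
)


def process(config: synthio.SimulationConfig) -> StudyRun:
    chroms, annotations, transcripts, truth = synthio.make_reference(config)
    reads_a, reads_b = synthio.simulate_libraries(truth, config)
    inserts_a, _ = preprocess.trim_library(reads_a, config.adapter3)
    inserts_b, _ = preprocess.trim_library(reads_b, config.adapter3)
    table = preprocess.collapse_reads(inserts_a, inserts_b)
    index = mapper.build_index(chroms)
    mapped, _, _ = mapper.locate(table, index)
    mapped_tab = mapper.mapped_table(table, mapped)
    classes = annotate.classify_tags(mapped, annotations)
    return StudyRun(
        config=config,
        chroms=chroms,
        annotations=annotations,
        transcripts=transcripts,
        truth=truth,
        table=table,
        mapped=mapped,
        mapped_table=mapped_tab,
        classes=classes,
        known_matures=set(synthio.known_mature_fasta(truth).values()),
    )


@pytest.fixture(scope="session")
def study() -> StudyRun:
    """Small synthetic experiment shared across tests (fixed seed)."""
    return process(MINI_CONFIG)


@pytest.fixture(scope="session")
def noise_free_study() -> StudyRun:
    """Same layout with dispersion 0: counts are exactly their expectations."""
    from dataclasses import replace

    return process(replace(MINI_CONFIG, dispersion=0.0, fold_palette=(-2.0, 0.0, 2.0)))
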