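"""Shared fixtures: small genomes and a mapped mini-scenario."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import evoreseq as er
from evoreseq import mapping, pipeline

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_genome() -> er.Genome:
    return er.generate_reference(1, [20_000], gc=0.38, seed=11)


@pytest.fixture(scope="session")
def small_scenario():
    """A compact evolved/parent simulation: 60 kb genome, 5x inverted
    amplification of a ~5 kb segment, 4 SNPs, 35x/28x depths.

    Mapped once per session; used by several module tests.
    """
    cfg = dataclasses.replace(
        pipeline.PipelineConfig(),
        genome_length=60_000,
        amp_left=30_011,
        amp_length=5_038,
        cbs_permutations=300,
    )
    reference, evolved, truth, reads_evo, reads_par = pipeline.demo_scenario(cfg, seed=3)
    index = mapping.build_index(reference, cfg.read_length)
    mask = mapping.mappability_mask(reference, cfg.read_length, index=index)
    data = {}
    for strain, reads in (("evolved", reads_evo), ("parent", reads_par)):
        alns, unmapped = mapping.map_reads(reads, index, cfg.max_mismatches)
        track, pile = mapping.pileup(alns, reference)
        data[strain] = {
            "alignments": alns,
            "unmapped": unmapped,
            "track": track,
            "pileup": pile,
        }
    return {
        "config": cfg,
        "reference": reference,
        "evolved": evolved,
        "truth": truth,
        "index": index,
        "mask": mask,
        "data": data,
    }
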