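"""Shared fixtures: a tiny hand-built genome plus lazily-computed objects
from the default synthetic scenario (session-scoped; several acceptance
checks share them)."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from hetmig.annotation import build_exclusive_partition, define_promoters
from hetmig.genome import GenomeTable
from hetmig.peaks import IslandCallerParams, call_islands, score_windows
from hetmig.synthetic import MARKS, SyntheticScenario, generate_annotation, simulate_chip_reads


@pytest.fixture
def toy_genome() -> GenomeTable:
    return GenomeTable([("chr1", 10_000), ("chr2", 5_000)])


@pytest.fixture(scope="session")
def scenario() -> SyntheticScenario:
    return SyntheticScenario(seed=1)


@pytest.fixture(scope="session")
def catalog(scenario):
    cat, _ = generate_annotation(scenario)
    return cat


@pytest.fixture(scope="session")
def partition(scenario, catalog):
    genome = scenario.genome()
    promoters = define_promoters(catalog.genes, genome)
    return build_exclusive_partition(catalog, promoters, genome)


@pytest.fixture(scope="session")
def chip_tracks(scenario, catalog):
    """All mark/condition read sets plus their planted-domain truths."""
    tracks, truths = {}, {}
    for cond in ("control", "migrating"):
        for mark in MARKS + ("input",):
            reads, tr = simulate_chip_reads(scenario, mark, cond, catalog=catalog)
            tracks[(mark, cond)] = reads
            truths[(mark, cond)] = tr.domains[(mark, cond)]
    return tracks, truths


@pytest.fixture(scope="session")
def called_islands(scenario, chip_tracks):
    tracks, _ = chip_tracks
    genome = scenario.genome()
    params = IslandCallerParams()
    out = {}
    for cond in ("control", "migrating"):
        control = tracks[("input", cond)]
        for mark in MARKS:
            scored = score_windows(tracks[(mark, cond)], params, genome)
            out[(mark, cond)] = call_islands(scored, control, params)
    return out


def overlap_bp(intervals_a, intervals_b) -> int:
    """Brute-ish total overlap between two interval lists (test helper)."""
    total = 0
    for a in intervals_a:
        for b in intervals_b:
            if a.chrom == b.chrom and a.start < b.end and b.start < a.end:
                total += min(a.end, b.end) - max(a.start, b.start)
    return total
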