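"""Shared fixtures: hand-built alignments and small simulated datasets."""

from __future__ import annotations

import numpy as np
import pytest

from invpop.io import GeneAnnotation, HaplotypeAlignment
from invpop.simulate import ClassSample, CoalescentConfig, simulate_arrangements


def make_aln(
    seqs: dict[str, str],
    arrangement: dict[str, str] | str = "A",
    population: dict[str, str] | str = "P",
    outgroup_id: str | None = None,
) -> HaplotypeAlignment:
    """Build an alignment from {id: sequence}; labels may be shared scalars."""
    ids = list(seqs)
    matrix = np.vstack(
        [np.frombuffer(seqs[s].upper().encode(), dtype=np.uint8) for s in ids]
    )
    arr = [
        None
        if s == outgroup_id
        else (arrangement if isinstance(arrangement, str) else arrangement[s])
        for s in ids
    ]
    pop = [
        None
        if s == outgroup_id
        else (population if isinstance(population, str) else population[s])
        for s in ids
    ]
    return HaplotypeAlignment(ids, matrix, arr, pop, outgroup_id)


@pytest.fixture
def two_class_aln():
    """Two clearly differentiated 4-sequence classes on 8 columns."""
    seqs = {
        "a1": "AAAACCGG",
        "a2": "AAAACCGG",
        "a3": "AAAACCGT",
        "a4": "AAAACCGG",
        "b1": "GGAACCTT",
        "b2": "GGAACCTT",
        "b3": "GGAACCTT",
        "b4": "GGATCCTT",
    }
    arr = {s: ("A" if s.startswith("a") else "B") for s in seqs}
    return make_aln(seqs, arr)


@pytest.fixture(scope="session")
def sim_pair():
    """One ancestral + one derived class, outgroup attached; deterministic."""
    cfg = CoalescentConfig(
        classes=[
            ClassSample("anc", "P", 10, 0.0),
            ClassSample("derived", "P", 10, 1500.0),
        ],
        locus_length=1500,
        exon_intervals=[(0, 600)],
        theta_per_site=0.008,
        rho_per_site=0.005,
        flux_rate=0.2,
        outgroup_divergence=0.17,
        ne=1000,
        seed=20,
    )
    aln, truth = simulate_arrangements(cfg)
    return cfg, aln, truth


@pytest.fixture
def coding_annotation():
    return GeneAnnotation("g", [(0, 600)], frame=0)
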