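import numpy as np
import pandas as pd
import pytest

from synchrodiff.core import GenomicInterval, IntervalSet, insertion_track
from synchrodiff.simulate import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def small_study():
    """Desk-scale simulated study shared across test modules."""
    cfg = SimulationConfig(
        seed=11,
        chrom_lengths={"chr1": 100_000, "chr2": 100_000},
        n_open_regions=40,
        n_genes=120,
        n_motif_sites=60,
        n_enhancers=14,
        bias={"ACGTAC": 2.0},
    )
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def study_tracks(small_study):
    """Normalised insertion tracks per time point (first two replicates)."""
    chrom_lengths = {c: len(s) for c, s in small_study.sequences.items()}
    return {
        t: [insertion_track(rep, chrom_lengths, normalise=True) for rep in reps]
        for t, reps in small_study.atac.items()
    }


@pytest.fixture(scope="session")
def study_regions(small_study):
    return IntervalSet(
        GenomicInterval(r.chrom, r.start, r.end)
        for _, r in small_study.truth.regions.iterrows()
    )


def make_intervals(triples):
    return IntervalSet(GenomicInterval(c, s, e) for c, s, e in triples)
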