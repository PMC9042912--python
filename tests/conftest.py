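import numpy as np
import pytest

from peakfactor.attribution import ConditionQuad
from peakfactor.intervals import (
    PeakSet,
    filter_redundant,
    idr_filter,
    replicate_reproducible,
)
from peakfactor.io_formats import GeneModel, GenomicInterval
from peakfactor.synthetic import make_genes, make_genome, plant_peaks


def make_peaks(coords, label="", **kwargs) -> PeakSet:
    """PeakSet from (chrom, start, end[, name]) tuples."""
    ivs = []
    for i, c in enumerate(coords):
        chrom, start, end = c[:3]
        name = c[3] if len(c) > 3 else f"p{i}"
        ivs.append(GenomicInterval(chrom, start, end, name=name, **kwargs))
    return PeakSet(ivs, label=label)


def random_intervals(rng, n, chroms=("chr1",), max_pos=10_000, max_len=200):
    out = []
    for i in range(n):
        chrom = chroms[rng.integers(0, len(chroms))]
        start = int(rng.integers(0, max_pos))
        length = int(rng.integers(1, max_len))
        out.append(GenomicInterval(chrom, start, start + length, name=f"r{i}"))
    return out


def preprocess_condition(replicates, idr_threshold=0.05, min_overlap=1):
    """The per-condition preprocessing chain: IDR filter, replicate
    reproducibility, redundancy filter."""
    current = idr_filter(replicates[0], idr_threshold)
    for nxt in replicates[1:]:
        current = replicate_reproducible(current, idr_filter(nxt, idr_threshold),
                                         min_overlap)
    return filter_redundant(current, min_overlap)


def quad_from_dataset(dataset) -> ConditionQuad:
    conds = {}
    for cond, reps in dataset.peaks.items():
        key = cond.lower().replace("-", "_")
        conds[key] = preprocess_condition(reps).relabel(key)
    return ConditionQuad.from_dict(conds)


@pytest.fixture(scope="session")
def default_genome():
    return make_genome(seed=11)


@pytest.fixture(scope="session")
def default_genes(default_genome):
    return make_genes(default_genome, seed=11)


@pytest.fixture(scope="session")
def noiseless_dataset(default_genome, default_genes):
    """Default study counts (300/100/50/200) with zero jitter and noise."""
    return plant_peaks(default_genome, default_genes, jitter_sd=0.0,
                       noise_rate=0.0, seed=11)


@pytest.fixture(scope="session")
def noisy_dataset(default_genome, default_genes):
    """Default study conditions: 20-bp jitter, 10% noise peaks."""
    return plant_peaks(default_genome, default_genes, seed=11)


@pytest.fixture(scope="session")
def small_genes():
    return [
        GeneModel("geneA", "chr1", "+", 10_000, 14_000,
                  exons=((10_000, 10_500), (13_000, 14_000))),
        GeneModel("geneB", "chr1", "-", 30_000, 33_000,
                  exons=((30_000, 30_800), (32_000, 33_000))),
        GeneModel("geneC", "chr2", "+", 5_000, 9_000, exons=((5_000, 9_000),)),
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
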