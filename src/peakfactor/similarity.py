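"""Sample-similarity computations on consensus accessibility peaks.

Samples are compared only on consensus peaks — regions covered by at
least one peak in *every* input set, merged to their union span (the
strictest reading of "overlapping peaks across conditions", which
guarantees every sample has a defined score for every consensus
region).  Similarity is the Pearson correlation of per-peak scores, and
the similarity network uses edge length 1 - r.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import GenomicInterval
from .intervals import PeakSet

__all__ = ["SimilarityMatrix", "consensus_peaks", "pearson_matrix", "similarity_edges"]


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric Pearson correlations between samples, unit diagonal."""

    frame: pd.DataFrame
    consensus_peak_count: int | None = None

    def __post_init__(self):
        values = self.frame.to_numpy()
        if values.shape[0] != values.shape[1]:
            raise ValueError("similarity matrix must be square")
        if not np.allclose(values, values.T, atol=1e-12):
            raise ValueError("similarity matrix must be symmetric")
        if not np.allclose(np.diag(values), 1.0, atol=1e-12):
            raise ValueError("similarity matrix diagonal must be 1")
        if np.any(values < -1 - 1e-12) or np.any(values > 1 + 1e-12):
            raise ValueError("correlations must lie in [-1, 1]")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)


def consensus_peaks(peaksets: list[PeakSet]) -> PeakSet:
    """Union-span regions covered by >= 1 peak of every input set."""
    if len(peaksets) < 2:
        raise ValueError("consensus requires at least 2 peak sets")
    records = []  # (chrom, start, end, set_index)
    for si, ps in enumerate(peaksets):
        for iv in ps:
            records.append((iv.chrom, iv.start, iv.end, si))
    records.sort()
    out = []
    n_sets = len(peaksets)
    i = 0
    cluster_idx = 0
    while i < len(records):
        chrom, start, end, si = records[i]
        members = {si}
        span_start, span_end = start, end
        i += 1
        while i < len(records) and records[i][0] == chrom and records[i][1] < span_end:
            span_end = max(span_end, records[i][2])
            members.add(records[i][3])
            i += 1
        if len(members) == n_sets:
            out.append(GenomicInterval(chrom, span_start, span_end,
                                       name=f"consensus_{cluster_idx}"))
            cluster_idx += 1
    return PeakSet(out, label="consensus")


def pearson_matrix(scores: pd.DataFrame) -> SimilarityMatrix:
    """Pearson correlation between all sample pairs of a samples x peaks table."""
    values = scores.to_numpy(dtype=float)
    if values.shape[1] < 2:
        raise ValueError("need >= 2 peaks per sample to correlate")
    stds = values.std(axis=1)
    constant = np.where(stds == 0)[0]
    if constant.size:
        raise ValueError(
            f"sample {scores.index[constant[0]]!r} has a constant score vector")
    corr = np.corrcoef(values)
    corr = np.clip(corr, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    corr = (corr + corr.T) / 2.0
    frame = pd.DataFrame(corr, index=scores.index, columns=scores.index)
    return SimilarityMatrix(frame=frame, consensus_peak_count=values.shape[1])


def similarity_edges(matrix: SimilarityMatrix) -> pd.DataFrame:
    """Complete-graph edge list with length 1 - r (r = 1 -> length 0)."""
    ids = matrix.sample_ids
    rows = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            r = float(matrix.frame.iat[i, j])
            rows.append({"sample_a": ids[i], "sample_b": ids[j],
                         "r": r, "length": 1.0 - r})
    return pd.DataFrame(rows, columns=["sample_a", "sample_b", "r", "length"])
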