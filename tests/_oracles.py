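"""Independent brute-force oracles the implementation is checked against.

Everything here is deliberately naive — O(n*m) double loops, exhaustive
enumeration, direct formula evaluation — and shares no code with the
package's sweep/searchsorted implementations.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from peakfactor.io_formats import GenomicInterval


def brute_overlaps(a: GenomicInterval, b: GenomicInterval, min_overlap: int = 1) -> bool:
    return (a.chrom == b.chrom
            and min(a.end, b.end) - max(a.start, b.start) >= min_overlap)


def brute_unique(query, reference, min_overlap: int = 1):
    """Query intervals overlapping nothing in the reference (double loop)."""
    out = []
    for q in query:
        if not any(brute_overlaps(q, r, min_overlap) for r in reference):
            out.append(q)
    return out


def brute_overlapping(query, reference, min_overlap: int = 1):
    out = []
    for q in query:
        if any(brute_overlaps(q, r, min_overlap) for r in reference):
            out.append(q)
    return out


def brute_symmetric(set_p, set_q, min_overlap: int = 1):
    return brute_unique(set_p, set_q, min_overlap) + brute_unique(set_q, set_p, min_overlap)


def brute_consensus(peaksets, min_overlap: int = 1):
    """Union-span components containing >= 1 member of every set.

    Builds the full pairwise overlap graph and closes components by
    repeated scanning (no sorting, no sweeping).
    """
    pooled = [(iv, si) for si, ps in enumerate(peaksets) for iv in ps]
    n = len(pooled)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if brute_overlaps(pooled[i][0], pooled[j][0], min_overlap):
                parent[find(i)] = find(j)
    comps: dict[int, list[int]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(i)
    spans = []
    for members in comps.values():
        sets_present = {pooled[i][1] for i in members}
        if len(sets_present) == len(peaksets):
            ivs = [pooled[i][0] for i in members]
            spans.append((ivs[0].chrom,
                          min(iv.start for iv in ivs),
                          max(iv.end for iv in ivs)))
    return sorted(spans)


def brute_classify(peak, genes, halfwidth: int = 3000):
    """Direct per-gene evaluation of the feature-classification rules.

    Returns (feature_class, gene_id) mirroring promoter > exonic >
    intronic > intergenic precedence with nearest-TSS assignment.
    """
    on_chrom = [g for g in genes if g.chrom == peak.chrom]
    if not on_chrom:
        return "intergenic", None

    def nearest(cands):
        best = min(abs(peak.start - g.tss) for g in cands)
        tied = [g for g in cands if abs(peak.start - g.tss) == best]
        return min(tied, key=lambda g: g.gene_id).gene_id

    prom = [g for g in on_chrom
            if peak.start < g.tss + halfwidth + 1 and peak.end > g.tss - halfwidth]
    if prom:
        return "promoter", nearest(prom)
    exonic = [g for g in on_chrom
              if any(peak.start < e and peak.end > s for (s, e) in g.exons)]
    if exonic:
        return "exonic", nearest(exonic)
    intronic = [g for g in on_chrom
                if peak.start < g.gene_end and peak.end > g.gene_start]
    if intronic:
        return "intronic", nearest(intronic)
    return "intergenic", nearest(on_chrom)


def brute_nearest_tss(peak, genes):
    on_chrom = [g for g in genes if g.chrom == peak.chrom]
    if not on_chrom:
        return None, None
    best = min(abs(peak.start - g.tss) for g in on_chrom)
    tied = sorted((g for g in on_chrom if abs(peak.start - g.tss) == best),
                  key=lambda g: g.gene_id)
    gene = tied[0]
    d = peak.start - gene.tss
    return gene.gene_id, (-d if gene.strand == "-" else d)


def enum_hypergeom_upper(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) by direct summation of hypergeometric point masses."""
    total = math.comb(N, n)
    acc = 0
    for x in range(k, min(n, K) + 1):
        if n - x > N - K:
            continue
        acc += math.comb(K, x) * math.comb(N - K, n - x)
    return acc / total


def enum_kmer_scores(motif):
    """All k-mer log-odds scores with their background probabilities."""
    lom = np.log2(motif.probs) - np.log2(motif.background)
    scores, probs = [], []
    for kmer in itertools.product(range(4), repeat=motif.width):
        scores.append(sum(lom[i, c] for i, c in enumerate(kmer)))
        probs.append(math.prod(motif.background[c] for c in kmer))
    return np.array(scores), np.array(probs)


def bh_stepup(p_values):
    """Hand implementation of the Benjamini-Hochberg step-up rule."""
    p = list(p_values)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [None] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, p[i] * m / rank_from_top)
        adjusted[i] = running_min
    return adjusted
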