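"""Exact genomic-interval set algebra on called peak sets.

This is the bedtools-intersect analog the attribution procedure is built
on: two peaks overlap when they share at least ``min_overlap`` bases
(default 1, the bedtools convention) on the same chromosome under
half-open coordinates.  Peaks are treated as unstranded throughout —
ATAC peaks carry no strand.

Set operations never fabricate coordinates: every output span is either
an input span or the union span of mutually overlapping input spans.
The implementations are sorted-sweep / binary-search based,
O((n+m) log(n+m)); correctness is defined by the brute-force pairwise
oracle in the test suite.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Iterator, Sequence

import numpy as np

from .io_formats import GenomicInterval

__all__ = [
    "PeakSet",
    "overlaps",
    "unique_against",
    "overlapping_with",
    "symmetric_unique",
    "filter_redundant",
    "union_span",
    "idr_filter",
    "replicate_reproducible",
    "tn5_shift",
]


class PeakSet:
    """A labelled, per-chromosome sorted, exact-duplicate-free peak collection.

    Intervals sharing identical (chrom, start, end) are deduplicated on
    construction (first occurrence kept).  ``origins`` optionally maps an
    interval's coordinates to the label of the set it came from, used to
    track provenance through symmetric differences.
    """

    def __init__(self, intervals: Iterable[GenomicInterval] = (), label: str = "",
                 origins: dict[tuple[str, int, int], str] | None = None):
        by_chrom: dict[str, list[GenomicInterval]] = {}
        seen: set[tuple[str, int, int]] = set()
        for iv in intervals:
            if iv.coords in seen:
                continue
            seen.add(iv.coords)
            by_chrom.setdefault(iv.chrom, []).append(iv)
        for ivs in by_chrom.values():
            ivs.sort(key=lambda iv: (iv.start, iv.end))
        self._by_chrom = {c: by_chrom[c] for c in sorted(by_chrom)}
        self.label = label
        self.origins = {} if origins is None else dict(origins)
        self._arrays_cache: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return sum(len(v) for v in self._by_chrom.values())

    def __iter__(self) -> Iterator[GenomicInterval]:
        for chrom in self._by_chrom:
            yield from self._by_chrom[chrom]

    def __contains__(self, iv: GenomicInterval) -> bool:
        return iv.coords in self.coord_set()

    def __repr__(self) -> str:
        return f"PeakSet(label={self.label!r}, n={len(self)})"

    def chroms(self) -> list[str]:
        return list(self._by_chrom)

    def on_chrom(self, chrom: str) -> list[GenomicInterval]:
        return list(self._by_chrom.get(chrom, ()))

    def coord_set(self) -> set[tuple[str, int, int]]:
        return {iv.coords for iv in self}

    def arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """(starts, ends) as int64 arrays, sorted by (start, end)."""
        if chrom not in self._arrays_cache:
            ivs = self._by_chrom.get(chrom, ())
            starts = np.fromiter((iv.start for iv in ivs), dtype=np.int64, count=len(ivs))
            ends = np.fromiter((iv.end for iv in ivs), dtype=np.int64, count=len(ivs))
            self._arrays_cache[chrom] = (starts, ends)
        return self._arrays_cache[chrom]

    def relabel(self, label: str) -> "PeakSet":
        return PeakSet(self, label=label, origins=self.origins)


def overlaps(a: GenomicInterval, b: GenomicInterval, min_overlap: int = 1) -> bool:
    """True iff a and b share >= ``min_overlap`` bases on the same chromosome."""
    if a.chrom != b.chrom:
        return False
    return min(a.end, b.end) - max(a.start, b.start) >= min_overlap


def _overlap_mask(query: PeakSet, reference: PeakSet, chrom: str,
                  min_overlap: int) -> np.ndarray:
    """Boolean array: which query intervals on ``chrom`` overlap the reference."""
    q_starts, q_ends = query.arrays(chrom)
    r_starts, r_ends = reference.arrays(chrom)
    if q_starts.size == 0:
        return np.zeros(0, dtype=bool)
    if r_starts.size == 0:
        return np.zeros(q_starts.size, dtype=bool)
    if min_overlap == 1:
        # ref candidates with start < q.end; among them overlap iff max end > q.start
        prefix_max_end = np.maximum.accumulate(r_ends)
        hi = np.searchsorted(r_starts, q_ends, side="left")
        mask = np.zeros(q_starts.size, dtype=bool)
        nz = hi > 0
        mask[nz] = prefix_max_end[hi[nz] - 1] > q_starts[nz]
        return mask
    # General minimum-overlap: bounded candidate scan per query interval.
    max_len = int((r_ends - r_starts).max())
    mask = np.zeros(q_starts.size, dtype=bool)
    for i in range(q_starts.size):
        lo = np.searchsorted(r_starts, q_starts[i] - max_len, side="left")
        hi = np.searchsorted(r_starts, q_ends[i] - min_overlap, side="right")
        if hi > lo:
            ov = (np.minimum(q_ends[i], r_ends[lo:hi])
                  - np.maximum(q_starts[i], r_starts[lo:hi]))
            mask[i] = bool((ov >= min_overlap).any())
    return mask


def _split_by_overlap(query: PeakSet, reference: PeakSet,
                      min_overlap: int) -> tuple[list[GenomicInterval], list[GenomicInterval]]:
    unique: list[GenomicInterval] = []
    shared: list[GenomicInterval] = []
    for chrom in query.chroms():
        ivs = query.on_chrom(chrom)
        mask = _overlap_mask(query, reference, chrom, min_overlap)
        for iv, hit in zip(ivs, mask):
            (shared if hit else unique).append(iv)
    return unique, shared


def unique_against(query: PeakSet, reference: PeakSet,
                   min_overlap: int = 1) -> PeakSet:
    """Query peaks overlapping no reference peak (a subset of the query)."""
    unique, _ = _split_by_overlap(query, reference, min_overlap)
    return PeakSet(unique, label=query.label, origins=query.origins)


def overlapping_with(query: PeakSet, reference: PeakSet,
                     min_overlap: int = 1) -> PeakSet:
    """Query peaks overlapping >= 1 reference peak; the complement of
    :func:`unique_against` within the query."""
    _, shared = _split_by_overlap(query, reference, min_overlap)
    return PeakSet(shared, label=query.label, origins=query.origins)


def symmetric_unique(set_p: PeakSet, set_q: PeakSet,
                     min_overlap: int = 1) -> PeakSet:
    """The symmetric difference under the overlap relation.

    Peaks of P overlapping nothing in Q, together with peaks of Q
    overlapping nothing in P; every output interval records which set it
    came from in ``origins``.
    """
    from_p = unique_against(set_p, set_q, min_overlap)
    from_q = unique_against(set_q, set_p, min_overlap)
    origins = {iv.coords: set_p.label for iv in from_p}
    origins.update({iv.coords: set_q.label for iv in from_q})
    return PeakSet(list(from_p) + list(from_q),
                   label=f"unique({set_p.label},{set_q.label})",
                   origins=origins)


def _merge_group(members: Sequence[GenomicInterval]) -> GenomicInterval:
    """Union span of mutually overlapping intervals, metadata combined."""
    if len(members) == 1:
        return members[0]
    start = min(iv.start for iv in members)
    end = max(iv.end for iv in members)
    names = [iv.name for iv in members if iv.name != "."]
    scores = [iv.score for iv in members if iv.score is not None]
    idrs = [iv.idr for iv in members if iv.idr is not None]
    return GenomicInterval(
        chrom=members[0].chrom, start=start, end=end,
        name="|".join(names) if names else ".",
        score=max(scores) if scores else None,
        strand=".",
        idr=min(idrs) if idrs else None,
    )


def union_span(peak1: GenomicInterval, peak2: GenomicInterval) -> GenomicInterval:
    """Adjust two overlapping peaks to the extreme start/stop coordinates."""
    if peak1.chrom != peak2.chrom:
        raise ValueError(
            f"cannot merge peaks on different chromosomes "
            f"({peak1.chrom} vs {peak2.chrom})")
    if not overlaps(peak1, peak2):
        raise ValueError(
            f"cannot merge non-overlapping peaks "
            f"{peak1.chrom}:{peak1.start}-{peak1.end} and "
            f"{peak2.chrom}:{peak2.start}-{peak2.end}")
    if peak1.coords == peak2.coords:
        return peak1
    return _merge_group([peak1, peak2])


def filter_redundant(peaks: PeakSet, min_overlap: int = 1) -> PeakSet:
    """Remove redundancy: exact duplicates are dropped (on PeakSet
    construction) and any mutually overlapping intervals are merged into
    their union span, leaving a non-overlapping master list.  Idempotent.
    """
    merged: list[GenomicInterval] = []
    for chrom in peaks.chroms():
        group: list[GenomicInterval] = []
        group_end = None
        for iv in peaks.on_chrom(chrom):
            if group and iv.start <= group_end - min_overlap:
                group.append(iv)
                group_end = max(group_end, iv.end)
            else:
                if group:
                    merged.append(_merge_group(group))
                group = [iv]
                group_end = iv.end
        if group:
            merged.append(_merge_group(group))
    return PeakSet(merged, label=peaks.label, origins=peaks.origins)


def idr_filter(peaks: PeakSet, threshold: float = 0.05) -> PeakSet:
    """Keep reproducible peaks with IDR <= ``threshold`` (inclusive)."""
    kept = []
    for iv in peaks:
        if iv.idr is None:
            raise ValueError(
                f"peak {iv.name} ({iv.chrom}:{iv.start}-{iv.end}) carries no "
                "IDR annotation; cannot apply the IDR filter")
        if iv.idr <= threshold:
            kept.append(iv)
    return PeakSet(kept, label=peaks.label, origins=peaks.origins)


def replicate_reproducible(rep1: PeakSet, rep2: PeakSet,
                           min_overlap: int = 1) -> PeakSet:
    """Peaks of rep1 supported by rep2, spans extended to the union.

    Each rep1 peak overlapping >= 1 rep2 peak is kept with its span
    widened to the extreme start/stop over itself and all overlapping
    rep2 peaks; rep1's metadata (name, IDR, scores) is retained, with
    the summit offset rebased onto the new start.
    """
    out: list[GenomicInterval] = []
    for chrom in rep1.chroms():
        r_starts, r_ends = rep2.arrays(chrom)
        max_len = int((r_ends - r_starts).max()) if r_starts.size else 0
        for iv in rep1.on_chrom(chrom):
            if r_starts.size == 0:
                continue
            lo = np.searchsorted(r_starts, iv.start - max_len, side="left")
            hi = np.searchsorted(r_starts, iv.end, side="left")
            ov = (np.minimum(iv.end, r_ends[lo:hi])
                  - np.maximum(iv.start, r_starts[lo:hi]))
            hits = np.where(ov >= min_overlap)[0]
            if hits.size == 0:
                continue
            new_start = min(iv.start, int(r_starts[lo:hi][hits].min()))
            new_end = max(iv.end, int(r_ends[lo:hi][hits].max()))
            summit = None
            if iv.summit_offset is not None:
                absolute = iv.start + iv.summit_offset
                if new_start <= absolute < new_end:
                    summit = absolute - new_start
            out.append(dataclasses.replace(
                iv, start=new_start, end=new_end, summit_offset=summit))
    return PeakSet(out, label=rep1.label, origins=rep1.origins)


def tn5_shift(fragment_ends: Iterable[tuple[str, int, str]]) -> list[tuple[str, int, str]]:
    """Shift positive-strand Tn5 insertion positions 4 bp downstream.

    Centers reads on the transposase binding event; non-positive strands
    are left unchanged.
    """
    out = []
    for chrom, pos, strand in fragment_ends:
        if pos < 0:
            raise ValueError(f"negative position {pos} on {chrom}")
        out.append((chrom, pos + 4 if strand == "+" else pos, strand))
    return out
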