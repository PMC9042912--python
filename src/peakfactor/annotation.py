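"""Peak-to-gene assignment and genomic-feature classification.

A peak is a *promoter* peak when it overlaps the window +/- ``h`` bases
around a transcriptional start site (TSS; default h = 3000, the window
closed at both ends, i.e. [tss - h, tss + h + 1) internally); *exonic*
when it overlaps any annotated exon; *intronic* when it lies inside a
gene span without touching an exon; otherwise *intergenic*.  Precedence
is promoter > exonic > intronic > intergenic.

Every peak receives exactly one gene: among the genes satisfying the
winning feature class, the one whose TSS is nearest to the *start* of
the peak (that is the stated assignment rule, applied uniformly), ties
broken by lexicographically smaller gene_id.  The reported distance is
signed, ``peak.start - tss`` negated for minus-strand genes so that
upstream of the gene is always negative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .attribution import (
    CATEGORY_IL2,
    CATEGORY_SYN_IL2,
    CATEGORY_SYN_TCR,
    CATEGORY_TCR,
    AttributionResult,
    ConditionQuad,
)
from .io_formats import GeneModel, GenomicInterval
from .intervals import PeakSet

__all__ = [
    "PeakAnnotation",
    "PromoterMatrix",
    "GeneIndex",
    "classify_peak",
    "annotate_peaks",
    "nearest_tss",
    "genes_by_category",
    "venn_counts",
    "promoter_matrix",
    "tss_distance_distribution",
    "CATEGORY_SYN",
]

CATEGORY_SYN = "TCR+IL-2"

FEATURE_PROMOTER = "promoter"
FEATURE_EXONIC = "exonic"
FEATURE_INTRONIC = "intronic"
FEATURE_INTERGENIC = "intergenic"


@dataclass(frozen=True)
class PeakAnnotation:
    """One peak's feature class, assigned gene and signed TSS distance."""

    peak: GenomicInterval
    feature_class: str
    gene_id: str | None
    distance_to_tss: int | None


class GeneIndex:
    """Per-chromosome sorted arrays over a gene collection, built once."""

    def __init__(self, genes: Sequence[GeneModel]):
        self.genes = list(genes)
        self._by_chrom: dict[str, dict] = {}
        by_chrom: dict[str, list[GeneModel]] = {}
        for g in self.genes:
            by_chrom.setdefault(g.chrom, []).append(g)
        for chrom, glist in by_chrom.items():
            # sort by (tss, gene_id) so lexicographic tie-break is a stable argmin
            glist.sort(key=lambda g: (g.tss, g.gene_id))
            exon_rows = [(s, e, i) for i, g in enumerate(glist) for (s, e) in g.exons]
            exon_rows.sort()
            self._by_chrom[chrom] = {
                "genes": glist,
                "tss": np.array([g.tss for g in glist], dtype=np.int64),
                "span_start": np.array([g.gene_start for g in glist], dtype=np.int64),
                "span_end": np.array([g.gene_end for g in glist], dtype=np.int64),
                "exon_start": np.array([r[0] for r in exon_rows], dtype=np.int64),
                "exon_end": np.array([r[1] for r in exon_rows], dtype=np.int64),
                "exon_gene": np.array([r[2] for r in exon_rows], dtype=np.int64),
            }

    def chrom(self, chrom: str) -> dict | None:
        return self._by_chrom.get(chrom)

    def _nearest_among(self, peak_start: int, chrom_data: dict,
                       candidates: np.ndarray) -> GeneModel:
        tss = chrom_data["tss"][candidates]
        dist = np.abs(peak_start - tss)
        best = dist.min()
        # among equidistant genes, the lexicographically smaller gene_id
        tied = candidates[dist == best]
        return min((chrom_data["genes"][i] for i in tied), key=lambda g: g.gene_id)

    def nearest(self, peak: GenomicInterval) -> tuple[GeneModel | None, int | None]:
        data = self.chrom(peak.chrom)
        if data is None or not data["genes"]:
            return None, None
        candidates = np.arange(len(data["genes"]))
        gene = self._nearest_among(peak.start, data, candidates)
        return gene, _signed_distance(peak, gene)


def _signed_distance(peak: GenomicInterval, gene: GeneModel) -> int:
    d = peak.start - gene.tss
    return -d if gene.strand == "-" else d


def _as_index(genes) -> GeneIndex:
    return genes if isinstance(genes, GeneIndex) else GeneIndex(genes)


def classify_peak(peak: GenomicInterval, genes,
                  promoter_halfwidth: int = 3000) -> PeakAnnotation:
    """Classify one peak; see the module docstring for the rules."""
    index = _as_index(genes)
    if not index.genes:
        warnings.warn("empty gene collection: all peaks classified intergenic "
                      "with no assigned gene", stacklevel=2)
        return PeakAnnotation(peak, FEATURE_INTERGENIC, None, None)
    data = index.chrom(peak.chrom)
    if data is None:
        warnings.warn(
            f"no gene on chromosome {peak.chrom}; peak "
            f"{peak.name} left unassigned", stacklevel=2)
        return PeakAnnotation(peak, FEATURE_INTERGENIC, None, None)

    tss = data["tss"]
    h = promoter_halfwidth
    # promoter window [tss - h, tss + h + 1), closed at h on both sides
    prom = np.where((peak.start < tss + h + 1) & (peak.end > tss - h))[0]
    if prom.size:
        gene = index._nearest_among(peak.start, data, prom)
        return PeakAnnotation(peak, FEATURE_PROMOTER, gene.gene_id,
                              _signed_distance(peak, gene))
    ex_s, ex_e = data["exon_start"], data["exon_end"]
    ex_hit = np.where((peak.start < ex_e) & (peak.end > ex_s))[0]
    if ex_hit.size:
        cand = np.unique(data["exon_gene"][ex_hit])
        gene = index._nearest_among(peak.start, data, cand)
        return PeakAnnotation(peak, FEATURE_EXONIC, gene.gene_id,
                              _signed_distance(peak, gene))
    span_hit = np.where((peak.start < data["span_end"]) &
                        (peak.end > data["span_start"]))[0]
    if span_hit.size:
        gene = index._nearest_among(peak.start, data, span_hit)
        return PeakAnnotation(peak, FEATURE_INTRONIC, gene.gene_id,
                              _signed_distance(peak, gene))
    gene = index._nearest_among(peak.start, data, np.arange(len(data["genes"])))
    return PeakAnnotation(peak, FEATURE_INTERGENIC, gene.gene_id,
                          _signed_distance(peak, gene))


def annotate_peaks(peaks: Iterable[GenomicInterval], genes,
                   promoter_halfwidth: int = 3000) -> list[PeakAnnotation]:
    index = _as_index(genes)
    with warnings.catch_warnings():
        if index.genes:
            warnings.simplefilter("once")
        return [classify_peak(p, index, promoter_halfwidth) for p in peaks]


def nearest_tss(peak: GenomicInterval, genes) -> tuple[str | None, int | None]:
    """The gene minimising |peak.start - tss| on the peak's chromosome.

    Ties break to the lexicographically smaller gene_id; the returned
    distance is signed and strand-adjusted (upstream negative).  With no
    gene on the chromosome, (None, None) is returned with a warning.
    """
    index = _as_index(genes)
    gene, dist = index.nearest(peak)
    if gene is None:
        warnings.warn(f"no gene on chromosome {peak.chrom}; peak "
                      f"{peak.name} left unassigned", stacklevel=2)
        return None, None
    return gene.gene_id, dist


def annotation_frame(annotations: Sequence[PeakAnnotation]) -> pd.DataFrame:
    return pd.DataFrame([{
        "peak_id": a.peak.name,
        "chrom": a.peak.chrom,
        "start": a.peak.start,
        "end": a.peak.end,
        "feature_class": a.feature_class,
        "gene_id": a.gene_id,
        "distance_to_tss": a.distance_to_tss,
    } for a in annotations])


def genes_by_category(result: AttributionResult, genes,
                      promoter_halfwidth: int = 3000) -> dict[str, list[str]]:
    """Deduplicated assigned-gene lists per OCR category.

    Besides the two synergy branches, the key "TCR+IL-2" carries the
    union of both branches' genes (the gene-level synergy category used
    in the three-way comparisons).
    """
    index = _as_index(genes)
    out: dict[str, list[str]] = {}
    for cat, peaks in result.master_lists().items():
        anns = annotate_peaks(peaks, index, promoter_halfwidth)
        out[cat] = sorted({a.gene_id for a in anns if a.gene_id is not None})
    out[CATEGORY_SYN] = sorted(set(out[CATEGORY_SYN_TCR]) | set(out[CATEGORY_SYN_IL2]))
    return out


def venn_counts(gene_sets: Mapping[str, Iterable[str]]) -> dict[tuple[str, ...], int]:
    """Exclusive region counts of the k-way Venn over gene lists.

    Keys are tuples of category names (in the mapping's order) defining
    the region of genes belonging to exactly those categories; region
    counts sum to the size of the union.
    """
    names = list(gene_sets)
    if len(names) < 2:
        raise ValueError("venn_counts requires at least 2 categories")
    sets = {n: set(gene_sets[n]) for n in names}
    universe = set().union(*sets.values())
    counts: dict[tuple[str, ...], int] = {}
    for gene in universe:
        key = tuple(n for n in names if gene in sets[n])
        counts[key] = counts.get(key, 0) + 1
    return counts


@dataclass(frozen=True)
class PromoterMatrix:
    """Open/closed promoter status per (gene, condition).

    A cell is open iff >= 1 peak of that condition's set is
    promoter-classified for that gene.
    """

    frame: pd.DataFrame  # bool, genes x conditions
    missing_genes: tuple[str, ...] = ()


def promoter_matrix(conditions: Mapping[str, PeakSet] | ConditionQuad, genes,
                    gene_subset: Sequence[str] | None = None,
                    promoter_halfwidth: int = 3000) -> PromoterMatrix:
    """Promoter open/closed matrix across the condition peak sets."""
    if isinstance(conditions, ConditionQuad):
        conditions = {s.label: s for s in conditions.sets()}
    index = _as_index(genes)
    open_genes: dict[str, set[str]] = {}
    for label, peaks in conditions.items():
        anns = annotate_peaks(peaks, index, promoter_halfwidth)
        open_genes[label] = {a.gene_id for a in anns
                             if a.feature_class == FEATURE_PROMOTER and a.gene_id}
    all_ids = [g.gene_id for g in sorted(index.genes, key=lambda g: g.gene_id)]
    missing: tuple[str, ...] = ()
    if gene_subset is not None:
        known = set(all_ids)
        missing = tuple(g for g in gene_subset if g not in known)
        rows = [g for g in gene_subset if g in known]
    else:
        rows = all_ids
    frame = pd.DataFrame(
        {label: [g in open_genes[label] for g in rows] for label in conditions},
        index=pd.Index(rows, name="gene_id"), dtype=bool)
    return PromoterMatrix(frame=frame, missing_genes=missing)


def tss_distance_distribution(peaks: Iterable[GenomicInterval], genes,
                              bins=50) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of signed peak-start-to-TSS distances of assigned peaks.

    Returns (counts, bin_edges); counts sum to the number of peaks that
    received a gene assignment.
    """
    index = _as_index(genes)
    distances = [a.distance_to_tss
                 for a in annotate_peaks(peaks, index)
                 if a.distance_to_tss is not None]
    if not distances:
        edges = np.asarray(bins, dtype=float) if np.ndim(bins) else np.linspace(0, 1, int(bins) + 1)
        return np.zeros(len(edges) - 1, dtype=int), edges
    counts, edges = np.histogram(np.asarray(distances), bins=bins)
    return counts, edges
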