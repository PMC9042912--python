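"""The two-level peak-set comparison attributing open chromatin regions
(OCRs) to control by TCR signal strength, IL-2 signal strength, or both.

The design is a 2x2 factorial: TCR signal strength (N4 strong epitope vs
T4 weak epitope) crossed with IL-2 signalling (WT intact vs Il2ra mutant
impaired).  Level 1 forms, for each factor, the peaks *unique* between
the two cells that differ only in that factor:

    A = unique between WT-N4  and WT-T4    (TCR varies, IL-2 intact)
    B = unique between MUT-N4 and MUT-T4   (TCR varies, IL-2 impaired)
    X = unique between WT-N4  and MUT-N4   (IL-2 varies, TCR strong)
    Y = unique between WT-T4  and MUT-T4   (IL-2 varies, TCR weak)

"Unique between" is the symmetric difference under the overlap relation
(both directions kept, with provenance): the phrasing is directionless,
and only this reading lets the level-2 overlap of A and B capture
TCR-driven changes in both IL-2 backgrounds.

Level 2 then defines three master lists: TCR-controlled OCRs (peaks
conserved between A and B), IL-2-controlled OCRs (conserved between X
and Y), and synergy OCRs controlled by both signals (peaks unique of
A vs B, and of X vs Y).  Synergy is computed per branch, yielding two
lists whose near-identity is a reported diagnostic (branch consistency).
Each master list is redundancy-filtered, with overlapping peaks merged
to their extreme start/stop coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .intervals import (
    PeakSet,
    filter_redundant,
    overlapping_with,
    symmetric_unique,
)

__all__ = [
    "ConditionQuad",
    "AttributionResult",
    "BranchConsistency",
    "level1",
    "level2",
    "attribute",
    "branch_consistency",
    "category_summary",
    "CATEGORY_TCR",
    "CATEGORY_IL2",
    "CATEGORY_SYN_TCR",
    "CATEGORY_SYN_IL2",
]

CATEGORY_TCR = "TCR"
CATEGORY_IL2 = "IL-2"
CATEGORY_SYN_TCR = "TCR+IL-2 (TCR branch)"
CATEGORY_SYN_IL2 = "TCR+IL-2 (IL-2 branch)"


@dataclass(frozen=True)
class ConditionQuad:
    """The four cells of the 2x2 design, as validated peak sets."""

    wt_n4: PeakSet
    mut_n4: PeakSet
    wt_t4: PeakSet
    mut_t4: PeakSet

    def __post_init__(self):
        labels = [s.label for s in self.sets()]
        if len(set(labels)) != 4:
            raise ValueError(
                f"the four condition peak sets must carry distinct labels, got {labels}")

    def sets(self) -> tuple[PeakSet, PeakSet, PeakSet, PeakSet]:
        return (self.wt_n4, self.mut_n4, self.wt_t4, self.mut_t4)

    @classmethod
    def from_dict(cls, peaksets: dict[str, PeakSet]) -> "ConditionQuad":
        try:
            return cls(wt_n4=peaksets["wt_n4"], mut_n4=peaksets["mut_n4"],
                       wt_t4=peaksets["wt_t4"], mut_t4=peaksets["mut_t4"])
        except KeyError as exc:
            raise KeyError(f"missing condition {exc.args[0]!r} in the 2x2 design") from None


@dataclass(frozen=True)
class AttributionResult:
    """Level-1 unique sets and the three master OCR lists (synergy per branch)."""

    A: PeakSet
    B: PeakSet
    X: PeakSet
    Y: PeakSet
    tcr_ocrs: PeakSet
    il2_ocrs: PeakSet
    syn_tcr_branch: PeakSet
    syn_il2_branch: PeakSet
    counts: dict = field(default_factory=dict)

    def master_lists(self) -> dict[str, PeakSet]:
        return {
            CATEGORY_TCR: self.tcr_ocrs,
            CATEGORY_IL2: self.il2_ocrs,
            CATEGORY_SYN_TCR: self.syn_tcr_branch,
            CATEGORY_SYN_IL2: self.syn_il2_branch,
        }


def level1(quad: ConditionQuad, min_overlap: int = 1
           ) -> tuple[PeakSet, PeakSet, PeakSet, PeakSet]:
    """First-level comparison: the four symmetric unique sets A, B, X, Y."""
    A = symmetric_unique(quad.wt_n4, quad.wt_t4, min_overlap).relabel("A")
    B = symmetric_unique(quad.mut_n4, quad.mut_t4, min_overlap).relabel("B")
    X = symmetric_unique(quad.wt_n4, quad.mut_n4, min_overlap).relabel("X")
    Y = symmetric_unique(quad.wt_t4, quad.mut_t4, min_overlap).relabel("Y")
    return A, B, X, Y


def level2(A: PeakSet, B: PeakSet, X: PeakSet, Y: PeakSet,
           min_overlap: int = 1) -> AttributionResult:
    """Second-level comparison producing the three master OCR lists.

    TCR-controlled OCRs are the peaks conserved (overlapping) between A
    and B; IL-2-controlled OCRs likewise between X and Y; synergy OCRs
    are the peaks unique of A vs B (TCR branch) and of X vs Y (IL-2
    branch).  All four outputs are redundancy-filtered, conserved pairs
    collapsing to their union span.
    """
    tcr = filter_redundant(PeakSet(
        list(overlapping_with(A, B, min_overlap)) +
        list(overlapping_with(B, A, min_overlap)),
        label=CATEGORY_TCR), min_overlap)
    il2 = filter_redundant(PeakSet(
        list(overlapping_with(X, Y, min_overlap)) +
        list(overlapping_with(Y, X, min_overlap)),
        label=CATEGORY_IL2), min_overlap)
    syn_tcr = filter_redundant(
        symmetric_unique(A, B, min_overlap), min_overlap).relabel(CATEGORY_SYN_TCR)
    syn_il2 = filter_redundant(
        symmetric_unique(X, Y, min_overlap), min_overlap).relabel(CATEGORY_SYN_IL2)
    counts = {
        "A": len(A), "B": len(B), "X": len(X), "Y": len(Y),
        CATEGORY_TCR: len(tcr), CATEGORY_IL2: len(il2),
        CATEGORY_SYN_TCR: len(syn_tcr), CATEGORY_SYN_IL2: len(syn_il2),
    }
    return AttributionResult(A=A, B=B, X=X, Y=Y, tcr_ocrs=tcr, il2_ocrs=il2,
                             syn_tcr_branch=syn_tcr, syn_il2_branch=syn_il2,
                             counts=counts)


def attribute(quad: ConditionQuad, min_overlap: int = 1) -> AttributionResult:
    """Run both comparison levels on the 2x2 design."""
    return level2(*level1(quad, min_overlap), min_overlap=min_overlap)


@dataclass(frozen=True)
class BranchConsistency:
    """Agreement between the gene sets of the two synergy branches."""

    jaccard: float
    frac_tcr_branch_shared: float
    frac_il2_branch_shared: float
    genes_tcr_branch: frozenset
    genes_il2_branch: frozenset


def branch_consistency(result: AttributionResult, genes,
                       promoter_halfwidth: int = 3000) -> BranchConsistency:
    """Overlap of the genes associated with the two synergy branches.

    Returns the Jaccard fraction |G_tcr & G_il2| / |G_tcr | G_il2| plus
    both directional fractions.  If both branches annotate to no genes
    the fraction is defined as 1 with a warning.
    """
    from .annotation import annotate_peaks

    def gene_set(peaks: PeakSet) -> frozenset:
        anns = annotate_peaks(peaks, genes, promoter_halfwidth)
        return frozenset(a.gene_id for a in anns if a.gene_id is not None)

    g_tcr = gene_set(result.syn_tcr_branch)
    g_il2 = gene_set(result.syn_il2_branch)
    union = g_tcr | g_il2
    if not union:
        warnings.warn("both synergy branches are empty; branch consistency "
                      "defined as 1.0", stacklevel=2)
        return BranchConsistency(1.0, 1.0, 1.0, g_tcr, g_il2)
    inter = g_tcr & g_il2
    return BranchConsistency(
        jaccard=len(inter) / len(union),
        frac_tcr_branch_shared=len(inter) / len(g_tcr) if g_tcr else 1.0,
        frac_il2_branch_shared=len(inter) / len(g_il2) if g_il2 else 1.0,
        genes_tcr_branch=g_tcr,
        genes_il2_branch=g_il2,
    )


def category_summary(result: AttributionResult, genes=None,
                     promoter_halfwidth: int = 3000) -> pd.DataFrame:
    """Peak (and, with an annotation, gene) counts and percentages per category.

    Two denominators are reported, each labelled: ``pct_of_branch`` uses
    the branch total (conserved + unique within that comparison branch)
    and ``pct_of_master`` the grand master-list total (TCR + IL-2 + that
    row's synergy branch).  Neither denominator is privileged.
    """
    n_tcr = len(result.tcr_ocrs)
    n_il2 = len(result.il2_ocrs)
    n_syn_t = len(result.syn_tcr_branch)
    n_syn_i = len(result.syn_il2_branch)
    branch_totals = {
        CATEGORY_TCR: n_tcr + n_syn_t,
        CATEGORY_IL2: n_il2 + n_syn_i,
        CATEGORY_SYN_TCR: n_tcr + n_syn_t,
        CATEGORY_SYN_IL2: n_il2 + n_syn_i,
    }
    master_totals = {
        CATEGORY_TCR: n_tcr + n_il2 + n_syn_t,
        CATEGORY_IL2: n_il2 + n_tcr + n_syn_i,
        CATEGORY_SYN_TCR: n_tcr + n_il2 + n_syn_t,
        CATEGORY_SYN_IL2: n_tcr + n_il2 + n_syn_i,
    }
    rows = []
    gene_counts = None
    if genes is not None:
        from .annotation import genes_by_category
        per_cat = genes_by_category(result, genes, promoter_halfwidth)
        gene_counts = {c: len(per_cat.get(c, ())) for c in branch_totals}
    for cat, n in [(CATEGORY_TCR, n_tcr), (CATEGORY_IL2, n_il2),
                   (CATEGORY_SYN_TCR, n_syn_t), (CATEGORY_SYN_IL2, n_syn_i)]:
        row = {
            "category": cat,
            "n_peaks": n,
            "pct_of_branch": 100.0 * n / branch_totals[cat] if branch_totals[cat] else 0.0,
            "pct_of_master": 100.0 * n / master_totals[cat] if master_totals[cat] else 0.0,
        }
        if gene_counts is not None:
            row["n_genes"] = gene_counts[cat]
        rows.append(row)
    return pd.DataFrame(rows).set_index("category")
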