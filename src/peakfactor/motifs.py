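"""PWM motif scanning with exact p-values, per-category motif
enrichment, and the transcription-factor segregation PCA.

Scanning follows the FIMO conventions: sites are scored by log-odds
(base 2) of the motif probabilities against a background letter
distribution, both strands are scanned, and each score receives an
exact p-value P(score >= s) under the i.i.d. background null, computed
by dynamic programming over a discretised score lattice (default
resolution 1e-3 bits).  Observed scores are mapped onto the lattice
with a slack of one lattice unit per motif position, so reported
p-values are exact up to that discretisation.

A peak "has" a motif when >= 1 scanned site overlaps it
(presence/absence, not site counts); per-category enrichment is a
hypergeometric test of category peaks-with-hit against a background
peak set, BH-corrected across the whole motif x category matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .enrichment import bh_adjust, hypergeom_upper
from .io_formats import GenomicInterval, MotifModel
from .intervals import PeakSet, filter_redundant, overlapping_with

__all__ = [
    "MotifHit",
    "TfEnrichmentMatrix",
    "TfPcaResult",
    "logodds_score",
    "ScoreDistribution",
    "score_pvalue",
    "scan",
    "motif_category_enrichment",
    "tf_segregation_pca",
]

_ENCODE = np.full(256, -1, dtype=np.int8)
for _i, _c in enumerate("ACGT"):
    _ENCODE[ord(_c)] = _i
    _ENCODE[ord(_c.lower())] = _i
_COMPLEMENT = np.array([3, 2, 1, 0], dtype=np.int8)  # A<->T, C<->G


@dataclass(frozen=True)
class MotifHit:
    """A predicted binding site with its log-odds score and p-value."""

    motif_id: str
    chrom: str
    start: int
    end: int
    strand: str
    score: float
    p_value: float

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end,
                               name=self.motif_id, strand=self.strand)


def _logodds_matrix(motif: MotifModel) -> np.ndarray:
    return np.log2(motif.probs) - np.log2(motif.background)


def logodds_score(motif: MotifModel, kmer: str) -> float:
    """Sum over positions of log2(p[letter] / background[letter])."""
    if len(kmer) != motif.width:
        raise ValueError(f"kmer length {len(kmer)} != motif width {motif.width}")
    enc = _ENCODE[np.frombuffer(kmer.encode(), dtype=np.uint8)]
    if np.any(enc < 0):
        raise ValueError(f"kmer {kmer!r} contains letters outside ACGT")
    return float(_logodds_matrix(motif)[np.arange(motif.width), enc].sum())


class ScoreDistribution:
    """Exact null distribution of a motif's log-odds score by lattice DP.

    Scores are rounded to multiples of ``resolution`` bits per position;
    the DP convolves the per-position background-weighted score
    distributions.  ``pvalue`` allows a slack of ``width`` lattice units
    (one rounding error per position) when mapping a float score onto
    the lattice.
    """

    def __init__(self, motif: MotifModel, resolution: float = 1e-3,
                 logodds: np.ndarray | None = None):
        self.resolution = float(resolution)
        self.width = motif.width
        lom = _logodds_matrix(motif) if logodds is None else logodds
        self._int_matrix = np.rint(lom / self.resolution).astype(np.int64)
        bg = motif.background
        mins = self._int_matrix.min(axis=1)
        maxs = self._int_matrix.max(axis=1)
        self._min_sum = int(mins.sum())
        self._max_sum = int(maxs.sum())
        size = self._max_sum - self._min_sum + 1
        dist = np.zeros(size)
        dist[0] = 1.0
        offset = 0  # current dist[i] = P(sum == min_prefix + i)
        for i in range(self.width):
            new = np.zeros(size)
            for letter in range(4):
                shift = int(self._int_matrix[i, letter] - mins[i])
                if shift == 0:
                    new[: size] += bg[letter] * dist
                else:
                    new[shift:] += bg[letter] * dist[: size - shift]
            dist = new
            offset += int(mins[i])
        # survival[i] = P(sum >= min_sum + i)
        self._survival = np.cumsum(dist[::-1])[::-1]
        self._survival = np.minimum(self._survival, 1.0)

    def int_scores(self, encoded_windows: np.ndarray) -> np.ndarray:
        """Lattice scores for an (n, width) array of encoded windows."""
        return self._int_matrix[np.arange(self.width), encoded_windows].sum(axis=1)

    def pvalue_int(self, int_score: np.ndarray | int) -> np.ndarray | float:
        idx = np.clip(np.asarray(int_score) - self._min_sum, 0,
                      self._survival.size - 1)
        out = self._survival[idx]
        out = np.where(np.asarray(int_score) > self._max_sum, self._survival[-1], out)
        if np.ndim(int_score) == 0:
            return float(out)
        return out

    def pvalue(self, score: float) -> float:
        """P(log-odds >= score) for a background-drawn k-mer."""
        if score == -np.inf:
            return 1.0
        t = int(np.rint(score / self.resolution)) - self.width
        if t <= self._min_sum:
            return 1.0
        if t > self._max_sum:
            return float(self._survival[-1])
        return float(self._survival[t - self._min_sum])

    def threshold_int(self, p_threshold: float) -> int:
        """Smallest lattice score whose p-value is <= ``p_threshold``."""
        idx = np.searchsorted(-self._survival, -p_threshold, side="left")
        if idx >= self._survival.size:
            return self._max_sum + 1  # unreachable: no score attains the threshold
        return self._min_sum + int(idx)


def score_pvalue(motif: MotifModel, score: float,
                 resolution: float = 1e-3) -> float:
    """Exact p-value of a log-odds score under the background null."""
    return ScoreDistribution(motif, resolution).pvalue(score)


def _revcomp_logodds(lom: np.ndarray) -> np.ndarray:
    # reverse positions and complement letters
    return lom[::-1, ::-1].copy()


def _window_scores(enc: np.ndarray, lom_int: np.ndarray, lom_float: np.ndarray,
                   width: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(valid, int_scores, float_scores) for all windows of ``enc``."""
    n = enc.size - width + 1
    if n <= 0:
        return (np.zeros(0, dtype=bool), np.zeros(0, dtype=np.int64),
                np.zeros(0))
    bad = (enc < 0).astype(np.int32)
    bad_in_window = np.convolve(bad, np.ones(width, dtype=np.int32), mode="valid")
    valid = bad_in_window == 0
    safe = np.where(enc < 0, 0, enc)
    iscore = np.zeros(n, dtype=np.int64)
    fscore = np.zeros(n)
    for i in range(width):
        letters = safe[i: i + n]
        iscore += lom_int[i, letters]
        fscore += lom_float[i, letters]
    return valid, iscore, fscore


def scan(peaks: PeakSet, genome: Mapping[str, str],
         motifs: Sequence[MotifModel], p_threshold: float = 1e-4,
         resolution: float = 1e-3, merge: bool = True) -> list[MotifHit]:
    """Scan peak sequences on both strands for motif sites with p <= threshold.

    Overlapping peaks are merged to their extreme start/stop coordinates
    before scanning (set ``merge=False`` if the set is already
    non-redundant).  Windows containing letters outside ACGT are
    skipped.  P-values on the reverse strand reuse the forward null,
    which assumes a strand-symmetric background (the uniform default
    is).
    """
    scanned = filter_redundant(peaks) if merge else peaks
    hits: list[MotifHit] = []
    prepared = []
    for motif in motifs:
        lom = _logodds_matrix(motif)
        dist = ScoreDistribution(motif, resolution, logodds=lom)
        lom_int = dist._int_matrix
        t_int = dist.threshold_int(p_threshold)
        prepared.append((motif, lom, lom_int, dist, t_int))
    for iv in scanned:
        if iv.chrom not in genome:
            raise ValueError(f"peak {iv.name}: contig {iv.chrom!r} absent from genome")
        contig = genome[iv.chrom]
        if iv.end > len(contig):
            raise ValueError(
                f"peak {iv.name} ({iv.chrom}:{iv.start}-{iv.end}) extends beyond "
                f"contig end {len(contig)}")
        seq = contig[iv.start: iv.end]
        enc = _ENCODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
        for motif, lom, lom_int, dist, t_int in prepared:
            w = motif.width
            for strand, lom_f, lom_i in (
                    ("+", lom, lom_int),
                    ("-", _revcomp_logodds(lom), _revcomp_logodds(lom_int))):
                valid, iscore, fscore = _window_scores(enc, lom_i, lom_f, w)
                keep = np.where(valid & (iscore >= t_int))[0]
                for j in keep:
                    hits.append(MotifHit(
                        motif_id=motif.motif_id,
                        chrom=iv.chrom,
                        start=iv.start + int(j),
                        end=iv.start + int(j) + w,
                        strand=strand,
                        score=float(fscore[j]),
                        p_value=float(dist.pvalue_int(int(iscore[j]))),
                    ))
    hits.sort(key=lambda h: (h.motif_id, h.chrom, h.start, h.strand))
    return hits


@dataclass(frozen=True)
class TfEnrichmentMatrix:
    """Per-(motif, category) enrichment of peaks containing the motif.

    ``log2_fold`` is a signed, lightly smoothed log2 ratio of the
    category hit rate to the background hit rate; ``p`` and ``q`` the
    hypergeometric p-values and their BH adjustment across all finite
    cells.  Columns of categories with no peaks are NaN-flagged.
    """

    log2_fold: pd.DataFrame
    p: pd.DataFrame
    q: pd.DataFrame
    hit_counts: pd.DataFrame


def _peaks_with_hit(peaks: PeakSet, hitset: PeakSet) -> int:
    if len(peaks) == 0 or len(hitset) == 0:
        return 0
    return len(overlapping_with(peaks, hitset))


def motif_category_enrichment(hits: Sequence[MotifHit],
                              categories: Mapping[str, PeakSet],
                              background: PeakSet) -> TfEnrichmentMatrix:
    """Hypergeometric enrichment of motif-bearing peaks per category.

    For each motif and category: universe = category peaks + background
    peaks, successes = peaks with >= 1 overlapping hit, draws = the
    category.  The test asks whether the category contains more
    motif-bearing peaks than the background rate predicts.
    """
    if len(background) == 0:
        raise ValueError("empty background peak set")
    motif_ids = sorted({h.motif_id for h in hits})
    cat_names = list(categories)
    empty = [c for c in cat_names if len(categories[c]) == 0]
    if empty:
        warnings.warn(f"categories with zero peaks: {empty}; their cells are "
                      "left undefined (NaN)", stacklevel=2)
    hit_by_motif = {
        m: PeakSet([h.interval for h in hits if h.motif_id == m], label=m)
        for m in motif_ids
    }
    fold = pd.DataFrame(np.nan, index=motif_ids, columns=cat_names)
    pval = pd.DataFrame(np.nan, index=motif_ids, columns=cat_names)
    counts = pd.DataFrame(0, index=motif_ids, columns=cat_names, dtype=int)
    n_bg = len(background)
    for m in motif_ids:
        hitset = hit_by_motif[m]
        k_bg = _peaks_with_hit(background, hitset)
        for c in cat_names:
            cat = categories[c]
            n_cat = len(cat)
            if n_cat == 0:
                continue
            k_cat = _peaks_with_hit(cat, hitset)
            counts.loc[m, c] = k_cat
            N = n_cat + n_bg
            K = k_cat + k_bg
            pval.loc[m, c] = hypergeom_upper(k_cat, K, n_cat, N)
            rate_cat = (k_cat + 0.5) / (n_cat + 1.0)
            rate_bg = (k_bg + 0.5) / (n_bg + 1.0)
            fold.loc[m, c] = np.log2(rate_cat / rate_bg)
    qval = pval.copy()
    flat = pval.to_numpy().ravel()
    finite = np.isfinite(flat)
    if finite.any():
        adjusted = np.full(flat.size, np.nan)
        adjusted[finite] = bh_adjust(flat[finite])
        qval = pd.DataFrame(adjusted.reshape(pval.shape),
                            index=pval.index, columns=pval.columns)
    return TfEnrichmentMatrix(log2_fold=fold, p=pval, q=qval, hit_counts=counts)


@dataclass(frozen=True)
class TfPcaResult:
    """PCA of the category x motif enrichment matrix.

    ``scores`` are the category coordinates on the principal
    components, ``loadings`` the per-motif loadings; each motif is
    assigned to the category of its largest reconstructed (centred)
    enrichment, and ``category_counts`` tallies those assignments.
    """

    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_ratio: np.ndarray
    assignment: pd.Series
    category_counts: pd.Series


def tf_segregation_pca(matrix: TfEnrichmentMatrix | pd.DataFrame,
                       n_components: int = 2,
                       scale: bool = False) -> TfPcaResult:
    """Which motifs account for segregating the OCR categories.

    Accepts the enrichment matrix (its ``log2_fold`` table is used) or
    any motifs x categories DataFrame.  The categories x motifs matrix
    is column-centred (optionally unit-scaled) and decomposed by SVD.
    """
    table = matrix.log2_fold if isinstance(matrix, TfEnrichmentMatrix) else matrix
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need >= 2 motifs and >= 2 categories")
    if table.isna().any().any():
        table = table.dropna(axis=1, how="any")
        if table.shape[1] < 2:
            raise ValueError("fewer than 2 categories with defined enrichment")
    M = table.T.to_numpy(dtype=float)  # categories x motifs
    centred = M - M.mean(axis=0, keepdims=True)
    if scale:
        sd = centred.std(axis=0, ddof=0)
        centred = centred / np.where(sd == 0, 1.0, sd)
    total_var = float((centred ** 2).sum())
    if total_var == 0:
        raise ValueError("enrichment matrix is constant: no variance to decompose")
    U, S, Vt = np.linalg.svd(centred, full_matrices=False)
    rank = int(np.sum(S > 1e-12 * S[0]))
    k = max(1, min(n_components, rank))
    comps = [f"PC{i + 1}" for i in range(k)]
    scores = pd.DataFrame(U[:, :k] * S[:k], index=table.columns, columns=comps)
    loadings = pd.DataFrame(Vt[:k].T, index=table.index, columns=comps)
    evr = (S ** 2) / (S ** 2).sum()
    # rank-k reconstruction of the centred matrix; each motif goes to the
    # category where its reconstructed (centred) enrichment is largest
    recon = (U[:, :k] * S[:k]) @ Vt[:k]
    assign_idx = np.argmax(recon, axis=0)
    assignment = pd.Series([table.columns[i] for i in assign_idx],
                           index=table.index, name="category")
    category_counts = assignment.value_counts().reindex(
        table.columns, fill_value=0)
    return TfPcaResult(scores=scores, loadings=loadings,
                       explained_variance_ratio=evr[:k],
                       assignment=assignment,
                       category_counts=category_counts)
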