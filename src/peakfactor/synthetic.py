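"""Synthetic inputs with planted ground truth for every pipeline stage.

The generator emulates the 2x2 factorial design of the study: four
conditions (WT-N4, MUT-N4, WT-T4, MUT-T4 — TCR signal strength crossed
with IL-2 signalling competence) with replicates, where each planted
open-chromatin locus follows one of four presence patterns over
(WT-N4, MUT-N4, WT-T4, MUT-T4):

    constitutive (1,1,1,1)   open everywhere
    TCR          (1,1,0,0)   open only with strong TCR signal
    IL2          (1,0,1,0)   open only with intact IL-2 signalling
    SYN          (1,0,0,0)   open only with both — the synergy pattern

plus noise peaks that appear in a single random replicate.  Planted
loci are pairwise separated by at least ``gap_min`` bases, so that
attribution on noiseless data recovers every planted category exactly.
Replicate peak boundaries receive Gaussian jitter; planted peaks carry
IDR values <= 0.05 and a configurable fraction of noise peaks carry
IDR > 0.05, so the IDR filter and the replicate-reproducibility step
are both exercised.  A configurable fraction of planted loci is placed
inside gene promoter windows for annotation tests, and known motif
sites can be written into peak sequences at per-category rates.

All outputs are pure functions of (parameters, seed): placement and
each condition/replicate emission use independent seed-derived RNG
streams, so regenerating one file is stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    GeneModel,
    GenomicInterval,
    MotifModel,
    write_fasta,
    write_gtf_lite,
    write_narrowpeak,
)
from .intervals import PeakSet

__all__ = [
    "CONDITIONS",
    "PATTERNS",
    "DEFAULT_COUNTS",
    "SyntheticDataset",
    "make_genome",
    "make_genes",
    "plant_peaks",
    "plant_motifs",
    "write_dataset",
]

CONDITIONS = ("WT-N4", "MUT-N4", "WT-T4", "MUT-T4")

PATTERNS: dict[str, tuple[int, int, int, int]] = {
    "constitutive": (1, 1, 1, 1),
    "TCR": (1, 1, 0, 0),
    "IL2": (1, 0, 1, 0),
    "SYN": (1, 0, 0, 0),
}

DEFAULT_COUNTS = {"constitutive": 300, "TCR": 100, "IL2": 50, "SYN": 200}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SyntheticDataset:
    """A generated genome, gene annotation, per-condition peak sets and truth.

    ``peaks`` maps condition label -> one PeakSet per replicate;
    ``truth`` has one row per planted locus and per noise peak.
    """

    genome: dict[str, str]
    genes: list[GeneModel]
    peaks: dict[str, list[PeakSet]]
    truth: pd.DataFrame
    params: dict = field(default_factory=dict)

    def condition_peaks(self, condition: str) -> list[PeakSet]:
        return self.peaks[condition]


def make_genome(n_chrom: int = 2, chrom_length: int = 1_000_000,
                seed: int = 0) -> dict[str, str]:
    """I.i.d. uniform ACGT contigs named chr1..chrN, reproducible per seed."""
    if n_chrom < 1 or chrom_length < 1:
        raise ValueError("n_chrom and chrom_length must be positive")
    rng = np.random.default_rng([seed, 101])
    genome = {}
    for i in range(n_chrom):
        draws = rng.integers(0, 4, size=chrom_length)
        genome[f"chr{i + 1}"] = _BASES[draws].tobytes().decode()
    return genome


def make_genes(genome: Mapping[str, str], n_genes: int = 400, seed: int = 0,
               length_range: tuple[int, int] = (800, 2_500),
               max_exons: int = 5, min_gap: int = 300) -> list[GeneModel]:
    """Random non-overlapping genes with 1-5 exons on both strands.

    Genes are laid out on a shuffled slot grid so that any requested
    count that fits is placed deterministically; insufficient space is
    an error.
    """
    rng = np.random.default_rng([seed, 202])
    lo, hi = length_range
    step = hi + min_gap
    slots = []
    for chrom, seq in genome.items():
        for pos in range(0, len(seq) - hi, step):
            slots.append((chrom, pos))
    if len(slots) < n_genes:
        raise ValueError(
            f"genome too small for {n_genes} genes (only {len(slots)} slots)")
    order = rng.permutation(len(slots))[:n_genes]
    placed = []
    for slot_idx in order:
        chrom, pos = slots[slot_idx]
        length = int(rng.integers(lo, hi + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        n_ex = int(rng.integers(1, max_exons + 1))
        # one exon inside each of n_ex equal blocks of the gene body
        block = length // n_ex
        exons = []
        for b in range(n_ex):
            b_lo = b * block
            b_hi = length if b == n_ex - 1 else (b + 1) * block
            width = int(rng.integers(1, max(2, (b_hi - b_lo) // 2 + 1)))
            start = int(rng.integers(b_lo, b_hi - width + 1))
            exons.append((pos + start, pos + start + width))
        placed.append((chrom, pos, pos + length, strand, tuple(sorted(exons))))
    placed.sort()
    return [
        GeneModel(gene_id=f"gene{i:04d}", chrom=chrom, strand=strand,
                  gene_start=start, gene_end=end, exons=exons)
        for i, (chrom, start, end, strand, exons) in enumerate(placed)
    ]


def _free_slots(genome: Mapping[str, str], occupied: Sequence[tuple[str, int, int]],
                width: int, gap_min: int) -> list[tuple[str, int]]:
    """Slot-grid starts in the space left free by padded occupied regions."""
    step = width + gap_min
    by_chrom: dict[str, list[tuple[int, int]]] = {c: [] for c in genome}
    for chrom, s, e in occupied:
        by_chrom[chrom].append((max(0, s - gap_min), e + gap_min))
    slots = []
    for chrom, seq in genome.items():
        blocks = sorted(by_chrom[chrom])
        cursor = 0
        for (bs, be) in blocks + [(len(seq), len(seq))]:
            pos = cursor
            while pos + width <= bs and pos + width <= len(seq):
                slots.append((chrom, pos))
                pos += step
            cursor = max(cursor, be)
    return slots


def plant_peaks(genome: Mapping[str, str], genes: Sequence[GeneModel],
                counts: Mapping[str, int] | None = None,
                peak_width: int = 300,
                jitter_sd: float = 20.0,
                noise_rate: float = 0.10,
                n_replicates: int = 2,
                gap_min: int = 1_000,
                promoter_fraction: float = 0.3,
                promoter_halfwidth: int = 3_000,
                noise_high_idr_fraction: float = 0.5,
                seed: int = 0) -> SyntheticDataset:
    """Plant category-patterned peak loci and emit per-replicate peak sets.

    Defaults are the study conditions the package is exercised under:
    300 constitutive + 100 TCR + 50 IL-2 + 200 synergy loci, 300-bp
    peaks, 20-bp boundary jitter, 10% noise peaks, two replicates.
    """
    counts = dict(DEFAULT_COUNTS if counts is None else counts)
    unknown = set(counts) - set(PATTERNS)
    if unknown:
        raise ValueError(f"unknown peak categories: {sorted(unknown)}")
    place_rng = np.random.default_rng([seed, 303])

    # --- choose loci positions -------------------------------------------
    n_planted = sum(counts.values())
    n_promoter = int(round(promoter_fraction * n_planted))
    chrom_len = {c: len(s) for c, s in genome.items()}
    promoter_sites: list[tuple[str, int, str]] = []  # (chrom, start, gene_id)
    last_on_chrom: dict[str, int] = {}
    for g in sorted(genes, key=lambda g: (g.chrom, g.tss)):
        if len(promoter_sites) == n_promoter:
            break
        start = g.tss - peak_width // 2
        if start < 0 or start + peak_width > chrom_len[g.chrom]:
            continue
        prev = last_on_chrom.get(g.chrom)
        if prev is not None and start < prev + peak_width + gap_min:
            continue
        promoter_sites.append((g.chrom, start, g.gene_id))
        last_on_chrom[g.chrom] = start
    if len(promoter_sites) < n_promoter:
        raise ValueError(
            f"cannot place {n_promoter} promoter loci with gap {gap_min}; "
            f"only {len(promoter_sites)} gene promoters available")

    noise_per = {
        cond: int(round(noise_rate * sum(
            counts[cat] for cat in counts if PATTERNS[cat][ci])))
        for ci, cond in enumerate(CONDITIONS)
    }
    n_noise_total = sum(noise_per.values()) * n_replicates
    occupied = [(c, s, s + peak_width) for (c, s, _g) in promoter_sites]
    slots = _free_slots(genome, occupied, peak_width, gap_min)
    n_free_needed = n_planted - n_promoter + n_noise_total
    if len(slots) < n_free_needed:
        raise ValueError(
            f"genome too small: need {n_free_needed} free loci, "
            f"have {len(slots)} slots")
    slot_order = place_rng.permutation(len(slots))
    free_iter = iter(slot_order)

    categories: list[str] = []
    for cat in PATTERNS:  # fixed category order; positions are shuffled anyway
        categories.extend([cat] * counts.get(cat, 0))
    promoter_pick = set(place_rng.choice(n_planted, size=n_promoter,
                                         replace=False).tolist())
    truth_rows = []
    loci: list[dict] = []
    prom_iter = iter(promoter_sites)
    for idx, cat in enumerate(categories):
        if idx in promoter_pick:
            chrom, start, gene_id = next(prom_iter)
            is_prom = True
        else:
            chrom, start = slots[next(free_iter)]
            gene_id = None
            is_prom = False
        locus = dict(locus_id=f"locus{idx:05d}", chrom=chrom, start=start,
                     end=start + peak_width, category=cat,
                     pattern=",".join(map(str, PATTERNS[cat])),
                     promoter=is_prom, gene_id=gene_id,
                     condition=None, replicate=None)
        loci.append(locus)
        truth_rows.append(locus)

    # --- emit per-condition, per-replicate peaks --------------------------
    peaks: dict[str, list[PeakSet]] = {}
    noise_counter = 0
    for ci, cond in enumerate(CONDITIONS):
        replicates = []
        for rep in range(n_replicates):
            rng = np.random.default_rng([seed, 404, ci, rep])
            ivs = []
            for locus in loci:
                if not PATTERNS[locus["category"]][ci]:
                    continue
                ivs.append(_emit_peak(locus["chrom"], locus["start"],
                                      locus["end"], chrom_len,
                                      f"{locus['locus_id']}_{cond}_rep{rep + 1}",
                                      jitter_sd, rng, idr_high=False))
            for _ in range(noise_per[cond]):
                chrom, start = slots[next(free_iter)]
                name = f"noise{noise_counter:05d}_{cond}_rep{rep + 1}"
                idr_high = bool(rng.random() < noise_high_idr_fraction)
                ivs.append(_emit_peak(chrom, start, start + peak_width,
                                      chrom_len, name, jitter_sd, rng,
                                      idr_high=idr_high))
                truth_rows.append(dict(
                    locus_id=f"noise{noise_counter:05d}", chrom=chrom,
                    start=start, end=start + peak_width, category="noise",
                    pattern="", promoter=False, gene_id=None,
                    condition=cond, replicate=rep + 1))
                noise_counter += 1
            replicates.append(PeakSet(ivs, label=f"{cond}_rep{rep + 1}"))
        peaks[cond] = replicates

    truth = pd.DataFrame(truth_rows)
    params = dict(counts=counts, peak_width=peak_width, jitter_sd=jitter_sd,
                  noise_rate=noise_rate, n_replicates=n_replicates,
                  gap_min=gap_min, promoter_fraction=promoter_fraction,
                  promoter_halfwidth=promoter_halfwidth,
                  noise_high_idr_fraction=noise_high_idr_fraction, seed=seed)
    return SyntheticDataset(genome=dict(genome), genes=list(genes),
                            peaks=peaks, truth=truth, params=params)


def _emit_peak(chrom: str, start: int, end: int, chrom_len: Mapping[str, int],
               name: str, jitter_sd: float, rng: np.random.Generator,
               idr_high: bool) -> GenomicInterval:
    if jitter_sd > 0:
        start = start + int(round(rng.normal(0, jitter_sd)))
        end = end + int(round(rng.normal(0, jitter_sd)))
    start = max(0, start)
    end = min(chrom_len[chrom], max(end, start + 1))
    width = end - start
    summit = width // 2 + (int(round(rng.normal(0, jitter_sd))) if jitter_sd > 0 else 0)
    summit = min(max(summit, 0), width - 1)
    score = float(min(1000, int(rng.lognormal(5.0, 0.5))))
    signal = float(np.round(rng.lognormal(1.5, 0.4), 4))
    neg_log10_p = float(np.round(rng.uniform(5.0, 50.0), 4))
    idr = (float(np.round(rng.uniform(0.051, 0.5), 5)) if idr_high
           else float(np.round(rng.uniform(0.0005, 0.05), 5)))
    return GenomicInterval(chrom=chrom, start=start, end=end, name=name,
                           score=score, strand=".", signal=signal,
                           neg_log10_p=neg_log10_p,
                           neg_log10_q=max(0.0, neg_log10_p - 1.0),
                           summit_offset=summit, idr=idr)


def plant_motifs(genome: Mapping[str, str], truth: pd.DataFrame,
                 motif: MotifModel, rates: Mapping[str, float],
                 seed: int = 0) -> tuple[dict[str, str], pd.DataFrame]:
    """Write the motif consensus into planted peaks at per-category rates.

    Returns the modified genome and a truth table with ``motif_id`` and
    ``motif_offset`` columns recording every insertion (offset relative
    to the unjittered locus start).
    """
    widths = truth["end"] - truth["start"]
    if motif.width >= int(widths.min()):
        raise ValueError("motif width must be smaller than the peak width")
    rng = np.random.default_rng([seed, 505])
    consensus = motif.consensus()
    buffers = {c: bytearray(s, "ascii") for c, s in genome.items()}
    motif_ids: list[str | None] = []
    offsets: list[float] = []
    for row in truth.itertuples(index=False):
        rate = float(rates.get(row.category, 0.0))
        if rate > 0 and rng.random() < rate:
            width = row.end - row.start
            offset = int(rng.integers(0, width - motif.width + 1))
            pos = row.start + offset
            buffers[row.chrom][pos: pos + motif.width] = consensus.encode()
            motif_ids.append(motif.motif_id)
            offsets.append(float(offset))
        else:
            motif_ids.append(None)
            offsets.append(np.nan)
    new_truth = truth.copy()
    new_truth["motif_id"] = motif_ids
    new_truth["motif_offset"] = offsets
    return {c: b.decode() for c, b in buffers.items()}, new_truth


def write_dataset(dataset: SyntheticDataset, outdir,
                  motifs: Sequence[MotifModel] = ()) -> dict[str, str]:
    """Write FASTA, GTF, per-condition/replicate narrowPeak (with the IDR
    column), the truth table and a parameter echo; returns the path map."""
    from .io_formats import write_motifs
    import yaml

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    write_fasta(dataset.genome, outdir / "genome.fa")
    paths["genome"] = str(outdir / "genome.fa")
    write_gtf_lite(dataset.genes, outdir / "genes.gtf")
    paths["gtf"] = str(outdir / "genes.gtf")
    for cond, replicates in dataset.peaks.items():
        safe = cond.replace("-", "_").lower()
        for rep_i, ps in enumerate(replicates, 1):
            path = outdir / f"{safe}_rep{rep_i}.narrowPeak"
            write_narrowpeak(ps, path, idr_column=True)
            paths[f"{safe}_rep{rep_i}"] = str(path)
    dataset.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    paths["truth"] = str(outdir / "truth.tsv")
    if motifs:
        write_motifs(motifs, outdir / "motifs.meme")
        paths["motifs"] = str(outdir / "motifs.meme")
    with open(outdir / "params.yaml", "w") as fh:
        yaml.safe_dump(dataset.params, fh, sort_keys=True)
    paths["params"] = str(outdir / "params.yaml")
    return paths
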