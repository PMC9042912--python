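"""Readers and writers for the external formats the pipeline touches.

All coordinates are held internally as 0-based half-open intervals (the BED
convention).  GTF input, which is 1-based inclusive, is converted on read;
the transcriptional start site (TSS) of a minus-strand gene is ``end - 1``,
the last covered base under the half-open convention.

Parsers validate aggressively and raise :class:`FormatError` carrying the
file name and the 1-based line number of the offending record.  In numeric
narrowPeak columns ``.`` (and the conventional ``-1`` sentinel in the
p-value, q-value and summit columns) is read as *absent*, never as zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "FormatError",
    "GenomicInterval",
    "GeneModel",
    "MotifModel",
    "read_narrowpeak",
    "write_narrowpeak",
    "read_bed",
    "write_bed",
    "read_gtf_lite",
    "write_gtf_lite",
    "read_motifs",
    "write_motifs",
    "read_fasta",
    "write_fasta",
    "read_score_table",
    "write_score_table",
    "read_gmt",
]

VALID_STRANDS = ("+", "-", ".")


class FormatError(ValueError):
    """A malformed record in an external file, addressed by line number."""

    def __init__(self, path, line_num: int | None, message: str):
        self.path = str(path)
        self.line_num = line_num
        where = f"{self.path}" if line_num is None else f"{self.path}:{line_num}"
        super().__init__(f"{where}: {message}")


@dataclass(frozen=True, slots=True)
class GenomicInterval:
    """A called peak (or any region) in 0-based half-open coordinates.

    ``score`` is the narrowPeak display score; ``signal`` the fold
    enrichment (column 7); ``neg_log10_p``/``neg_log10_q`` the -log10
    p/q-values; ``summit_offset`` the summit position relative to
    ``start``.  ``idr`` is an optional reproducibility annotation in
    [0, 1].  Missing numeric values are ``None``, not 0.
    """

    chrom: str
    start: int
    end: int
    name: str = "."
    score: float | None = None
    strand: str = "."
    signal: float | None = None
    neg_log10_p: float | None = None
    neg_log10_q: float | None = None
    summit_offset: int | None = None
    idr: float | None = None

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("interval chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.summit_offset is not None and self.summit_offset >= 0:
            if self.start + self.summit_offset >= self.end:
                raise ValueError(
                    f"summit_offset {self.summit_offset} falls outside "
                    f"{self.chrom}:{self.start}-{self.end}"
                )
        if self.idr is not None and not (0.0 <= self.idr <= 1.0):
            raise ValueError(f"idr must lie in [0, 1], got {self.idr}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def coords(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


@dataclass(frozen=True)
class GeneModel:
    """A gene with its exon structure, 0-based half-open.

    The TSS is strand-aware: ``gene_start`` on the plus strand and
    ``gene_end - 1`` on the minus strand.
    """

    gene_id: str
    chrom: str
    strand: str
    gene_start: int
    gene_end: int
    exons: tuple[tuple[int, int], ...] = ()

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene strand must be + or -, got {self.strand!r}")
        if not (0 <= self.gene_start < self.gene_end):
            raise ValueError(f"invalid gene span for {self.gene_id}")
        prev_end = None
        for (s, e) in self.exons:
            if not (self.gene_start <= s < e <= self.gene_end):
                raise ValueError(
                    f"exon ({s}, {e}) of {self.gene_id} outside gene span "
                    f"[{self.gene_start}, {self.gene_end})"
                )
            if prev_end is not None and s < prev_end:
                raise ValueError(f"exons of {self.gene_id} not sorted/disjoint")
            prev_end = e

    @property
    def tss(self) -> int:
        return self.gene_start if self.strand == "+" else self.gene_end - 1


def _normalize_probs(probs: np.ndarray, pseudocount: float) -> np.ndarray:
    shifted = probs + pseudocount
    return shifted / shifted.sum(axis=1, keepdims=True)


@dataclass(frozen=True, eq=False)
class MotifModel:
    """A position weight matrix over (A, C, G, T) with its background.

    ``probs`` holds the letter probabilities *after* pseudocount
    regularisation; every entry is strictly positive and each row sums
    to 1.  ``pseudocount`` records the value that was applied.
    """

    motif_id: str
    probs: np.ndarray
    background: np.ndarray
    pseudocount: float = 0.01

    def __post_init__(self):
        probs = np.asarray(self.probs, dtype=float)
        background = np.asarray(self.background, dtype=float)
        if probs.ndim != 2 or probs.shape[1] != 4:
            raise ValueError("probs must be a width x 4 matrix")
        if background.shape != (4,):
            raise ValueError("background must have 4 entries")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be non-negative")
        if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("motif rows must sum to 1 after normalization")
        if not math.isclose(background.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("background must sum to 1")
        if np.any(probs <= 0) or np.any(background <= 0):
            raise ValueError("probabilities must be strictly positive")
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "background", background)

    @classmethod
    def from_rows(
        cls,
        motif_id: str,
        rows: Sequence[Sequence[float]],
        background: Sequence[float] | None = None,
        pseudocount: float = 0.01,
        tol: float = 0.01,
    ) -> "MotifModel":
        """Build from raw probability rows, validating and regularising.

        Each raw row must sum to 1 within ``tol`` before the pseudocount
        is applied.
        """
        raw = np.asarray(rows, dtype=float)
        if raw.ndim != 2 or raw.shape[1] != 4:
            raise ValueError("motif rows must each have 4 letter probabilities")
        sums = raw.sum(axis=1)
        bad = np.where(np.abs(sums - 1.0) > tol)[0]
        if bad.size:
            raise ValueError(
                f"motif {motif_id!r}: row {bad[0] + 1} sums to {sums[bad[0]]:.4g}, "
                "not a probability distribution"
            )
        if background is None:
            background = np.full(4, 0.25)
        return cls(
            motif_id=motif_id,
            probs=_normalize_probs(raw, pseudocount),
            background=np.asarray(background, dtype=float),
            pseudocount=pseudocount,
        )

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in np.argmax(self.probs, axis=1))

    def information_content(self) -> float:
        """Total information content in bits relative to the background."""
        return float(
            np.sum(self.probs * (np.log2(self.probs) - np.log2(self.background)))
        )


# ---------------------------------------------------------------------------
# narrowPeak / BED


def _parse_int(value: str, what: str, path, ln: int) -> int:
    try:
        return int(value)
    except ValueError:
        raise FormatError(path, ln, f"non-integer {what}: {value!r}") from None


def _parse_opt_float(value: str, what: str, path, ln: int,
                     na_sentinel: bool = False) -> float | None:
    if value == ".":
        return None
    try:
        out = float(value)
    except ValueError:
        raise FormatError(path, ln, f"non-numeric {what}: {value!r}") from None
    if na_sentinel and out == -1:
        return None
    return out


def _build_interval(path, ln, **kwargs) -> GenomicInterval:
    try:
        return GenomicInterval(**kwargs)
    except ValueError as exc:
        raise FormatError(path, ln, str(exc)) from None


def read_narrowpeak(path, idr_column: bool = False) -> list[GenomicInterval]:
    """Read an ENCODE narrowPeak (BED6+4) file, order preserved.

    With ``idr_column=True`` an 11th column carrying a per-peak IDR value
    is required (a local extension used by the synthetic generator and
    the pipeline; plain narrowPeak files use the strict 10-column form).
    """
    n_fields = 11 if idr_column else 10
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) != n_fields:
                raise FormatError(
                    path, ln,
                    f"expected {n_fields} tab-separated fields, got {len(fields)}",
                )
            strand = fields[5]
            if strand not in VALID_STRANDS:
                raise FormatError(path, ln, f"invalid strand {strand!r} (field 6)")
            summit = _parse_int(fields[9], "summit offset (field 10)", path, ln)
            idr = None
            if idr_column:
                idr = _parse_opt_float(fields[10], "idr (field 11)", path, ln)
            out.append(_build_interval(
                path, ln,
                chrom=fields[0],
                start=_parse_int(fields[1], "start (field 2)", path, ln),
                end=_parse_int(fields[2], "end (field 3)", path, ln),
                name=fields[3],
                score=_parse_opt_float(fields[4], "score (field 5)", path, ln),
                strand=strand,
                signal=_parse_opt_float(fields[6], "signal (field 7)", path, ln),
                neg_log10_p=_parse_opt_float(
                    fields[7], "-log10 p (field 8)", path, ln, na_sentinel=True),
                neg_log10_q=_parse_opt_float(
                    fields[8], "-log10 q (field 9)", path, ln, na_sentinel=True),
                summit_offset=None if summit == -1 else summit,
                idr=idr,
            ))
    return out


def _fmt_opt(value: float | None, absent: str) -> str:
    if value is None:
        return absent
    if float(value).is_integer():
        return str(int(value))
    return repr(float(value))


def write_narrowpeak(intervals: Iterable[GenomicInterval], path,
                     idr_column: bool = False) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fields = [
                iv.chrom, str(iv.start), str(iv.end), iv.name,
                _fmt_opt(iv.score, "."), iv.strand,
                _fmt_opt(iv.signal, "."),
                _fmt_opt(iv.neg_log10_p, "-1"),
                _fmt_opt(iv.neg_log10_q, "-1"),
                str(-1 if iv.summit_offset is None else iv.summit_offset),
            ]
            if idr_column:
                fields.append(_fmt_opt(iv.idr, "."))
            fh.write("\t".join(fields) + "\n")


def read_bed(path) -> list[GenomicInterval]:
    """Read BED3/BED6; missing name/score/strand default to "."/0/"."."""
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(path, ln, "BED requires at least 3 columns")
            strand = fields[5] if len(fields) > 5 else "."
            if strand not in VALID_STRANDS:
                raise FormatError(path, ln, f"invalid strand {strand!r}")
            score = 0.0
            if len(fields) > 4:
                parsed = _parse_opt_float(fields[4], "score", path, ln)
                score = 0.0 if parsed is None else parsed
            out.append(_build_interval(
                path, ln,
                chrom=fields[0],
                start=_parse_int(fields[1], "start", path, ln),
                end=_parse_int(fields[2], "end", path, ln),
                name=fields[3] if len(fields) > 3 else ".",
                score=score,
                strand=strand,
            ))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            score = 0.0 if iv.score is None else iv.score
            fh.write("\t".join([
                iv.chrom, str(iv.start), str(iv.end), iv.name,
                _fmt_opt(score, "0"), iv.strand,
            ]) + "\n")


# ---------------------------------------------------------------------------
# GTF-lite


def _gtf_attributes(field: str, path, ln: int) -> dict[str, str]:
    attrs = {}
    for chunk in field.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        parts = chunk.split(None, 1)
        if len(parts) != 2:
            continue
        attrs[parts[0]] = parts[1].strip().strip('"')
    return attrs


def read_gtf_lite(path) -> list[GeneModel]:
    """Read gene and exon features from a GTF file into GeneModels.

    GTF's 1-based inclusive coordinates are converted to 0-based
    half-open on read.  Every feature must carry a ``gene_id``
    attribute; exons must fall inside their gene's span.
    """
    genes: dict[str, dict] = {}
    exons: list[tuple[str, int, int, int]] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(path, ln, f"expected 9 GTF fields, got {len(fields)}")
            feature = fields[2]
            if feature not in ("gene", "exon"):
                continue
            attrs = _gtf_attributes(fields[8], path, ln)
            if "gene_id" not in attrs:
                raise FormatError(path, ln, f"{feature} feature without gene_id")
            gene_id = attrs["gene_id"]
            start1 = _parse_int(fields[3], "start", path, ln)
            end1 = _parse_int(fields[4], "end", path, ln)
            start0, end0 = start1 - 1, end1  # 1-based inclusive -> half-open
            if start0 < 0 or start0 >= end0:
                raise FormatError(path, ln, f"invalid coordinates {start1}..{end1}")
            strand = fields[6]
            if feature == "gene":
                if strand not in ("+", "-"):
                    raise FormatError(path, ln, f"gene strand must be + or -, got {strand!r}")
                if gene_id in genes:
                    raise FormatError(path, ln, f"duplicate gene_id {gene_id!r}")
                genes[gene_id] = dict(
                    gene_id=gene_id, chrom=fields[0], strand=strand,
                    gene_start=start0, gene_end=end0, line=ln,
                )
            else:
                exons.append((gene_id, start0, end0, ln))
    grouped: dict[str, list[tuple[int, int]]] = {g: [] for g in genes}
    for gene_id, s, e, ln in exons:
        if gene_id not in genes:
            raise FormatError(path, ln, f"exon references unknown gene_id {gene_id!r}")
        g = genes[gene_id]
        if not (g["gene_start"] <= s < e <= g["gene_end"]):
            raise FormatError(
                path, ln,
                f"exon [{s}, {e}) of {gene_id!r} outside gene span "
                f"[{g['gene_start']}, {g['gene_end']})",
            )
        grouped[gene_id].append((s, e))
    out = []
    for gene_id, g in genes.items():
        try:
            out.append(GeneModel(
                gene_id=gene_id, chrom=g["chrom"], strand=g["strand"],
                gene_start=g["gene_start"], gene_end=g["gene_end"],
                exons=tuple(sorted(grouped[gene_id])),
            ))
        except ValueError as exc:
            raise FormatError(path, g["line"], str(exc)) from None
    out.sort(key=lambda g: (g.chrom, g.gene_start, g.gene_id))
    return out


def write_gtf_lite(genes: Iterable[GeneModel], path, source: str = "peakfactor") -> None:
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}";'
            fh.write("\t".join([
                g.chrom, source, "gene", str(g.gene_start + 1), str(g.gene_end),
                ".", g.strand, ".", attrs,
            ]) + "\n")
            for (s, e) in g.exons:
                fh.write("\t".join([
                    g.chrom, source, "exon", str(s + 1), str(e),
                    ".", g.strand, ".", attrs,
                ]) + "\n")


# ---------------------------------------------------------------------------
# MEME minimal motifs


def read_motifs(path, pseudocount: float = 0.01,
                background: Sequence[float] | None = None) -> list[MotifModel]:
    """Read a MEME minimal-format motif file.

    Raw probability rows must sum to 1 within 0.01; rows are then
    regularised with ``pseudocount``.  The file's background line is
    used unless ``background`` overrides it.
    """
    file_bg: np.ndarray | None = None
    motifs: list[MotifModel] = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            i += 1
            tokens = lines[i].split()
            # alternating letter / value pairs: A 0.25 C 0.25 ...
            try:
                vals = {tokens[j]: float(tokens[j + 1]) for j in range(0, len(tokens), 2)}
                file_bg = np.array([vals[c] for c in "ACGT"])
            except (ValueError, KeyError, IndexError):
                raise FormatError(path, i + 1, "malformed background frequency line") from None
        elif line.startswith("MOTIF"):
            tokens = line.split()
            if len(tokens) < 2:
                raise FormatError(path, i + 1, "MOTIF line without identifier")
            motif_id = tokens[1]
            i += 1
            while i < len(lines) and not lines[i].strip().startswith("letter-probability matrix"):
                if lines[i].strip().startswith("MOTIF"):
                    raise FormatError(path, i + 1, f"motif {motif_id!r} has no matrix")
                i += 1
            if i >= len(lines):
                raise FormatError(path, None, f"motif {motif_id!r} has no matrix")
            header = lines[i].strip()
            width = None
            for tok_a, tok_b in zip(header.split(), header.split()[1:]):
                if tok_a in ("w=", "w"):
                    width = int(tok_b)
            if "w=" in header and width is None:
                width = int(header.split("w=")[1].split()[0])
            rows = []
            i += 1
            while i < len(lines):
                stripped = lines[i].strip()
                if not stripped or stripped.startswith(("MOTIF", "URL")):
                    break
                values = stripped.split()
                if len(values) != 4:
                    raise FormatError(path, i + 1, f"expected 4 probabilities, got {len(values)}")
                try:
                    rows.append([float(v) for v in values])
                except ValueError:
                    raise FormatError(path, i + 1, "non-numeric probability") from None
                i += 1
            if width is not None and len(rows) != width:
                raise FormatError(path, None,
                                  f"motif {motif_id!r}: header says w={width}, got {len(rows)} rows")
            if not rows:
                raise FormatError(path, None, f"motif {motif_id!r} has an empty matrix")
            bg = background if background is not None else file_bg
            try:
                motifs.append(MotifModel.from_rows(motif_id, rows, background=bg,
                                                   pseudocount=pseudocount))
            except ValueError as exc:
                raise FormatError(path, None, str(exc)) from None
            continue
        i += 1
    return motifs


def write_motifs(motifs: Iterable[MotifModel], path) -> None:
    """Write MEME minimal format (the regularised probabilities)."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
        first = True
        for m in motifs:
            if first:
                bg = " ".join(f"{c} {v:.5f}" for c, v in zip("ACGT", m.background))
                fh.write(f"Background letter frequencies\n{bg}\n\n")
                first = False
            fh.write(f"MOTIF {m.motif_id}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {m.width}\n")
            for row in m.probs:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# FASTA / score tables / GMT


def read_fasta(path) -> dict[str, str]:
    """Read FASTA into a contig -> uppercase sequence mapping."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path, width: int = 70) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_score_table(path) -> pd.DataFrame:
    """Read a TSV score matrix into a samples x peaks DataFrame.

    On disk rows are peaks and columns are samples (header row = sample
    IDs, first column = peak IDs); the table is transposed on read.
    """
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if frame.shape[1] < 1:
        raise FormatError(path, None, "score table has no sample columns")
    try:
        frame = frame.astype(float)
    except ValueError as exc:
        raise FormatError(path, None, f"non-numeric score value ({exc})") from None
    return frame.T


def write_score_table(scores: pd.DataFrame, path) -> None:
    """Write a samples x peaks DataFrame as a peaks x samples TSV."""
    scores.T.to_csv(path, sep="\t", index_label="peak_id")


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT gene-set file into term -> gene list (descriptions dropped)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(path, ln, "GMT requires term, description, >=1 gene")
            genes = [g for g in fields[2:] if g]
            if not genes:
                raise FormatError(path, ln, f"term {fields[0]!r} has no genes")
            sets[fields[0]] = genes
    return sets
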