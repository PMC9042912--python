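"""End-to-end orchestration of the factorial accessibility analysis.

``run_pipeline`` executes, per condition: IDR filtering, replicate
reproducibility with union-span merging, redundancy filtering; then the
two-level attribution, peak-to-gene annotation, gene Venn counts,
optional over-representation analysis, optional motif scanning /
enrichment / TF-segregation PCA, and optional sample similarity.  Every
stage writes a tabular artifact; a MANIFEST records completed stages
and a summary JSON carries all counts plus run metadata.  The summary
contains no timestamps, so identical (inputs, config, seed) produce
byte-identical summaries.
"""

from __future__ import annotations

import difflib
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from . import __version__
from .annotation import (
    CATEGORY_SYN,
    GeneIndex,
    annotate_peaks,
    annotation_frame,
    genes_by_category,
    venn_counts,
)
from .attribution import (
    CATEGORY_IL2,
    CATEGORY_SYN_IL2,
    CATEGORY_SYN_TCR,
    CATEGORY_TCR,
    ConditionQuad,
    attribute,
    branch_consistency,
    category_summary,
)
from .enrichment import ora
from .io_formats import (
    read_fasta,
    read_gmt,
    read_gtf_lite,
    read_motifs,
    read_narrowpeak,
    read_score_table,
    write_bed,
)
from .intervals import PeakSet, filter_redundant, idr_filter, replicate_reproducible
from .motifs import motif_category_enrichment, scan, tf_segregation_pca
from .similarity import pearson_matrix, similarity_edges

__all__ = ["PipelineConfig", "PipelineError", "validate_config", "run_pipeline"]

logger = logging.getLogger(__name__)

CONDITION_KEYS = ("wt_n4", "mut_n4", "wt_t4", "mut_t4")

_DEFAULTS = dict(
    promoter_halfwidth=3000,
    idr_threshold=0.05,
    min_overlap_bp=1,
    motif_p_threshold=1e-4,
    ora_q_threshold=0.05,
    has_idr_column=True,
    seed=0,
)

_OPTIONAL_PATHS = ("gtf", "genome_fasta", "motifs", "gene_sets", "score_table")


class PipelineError(RuntimeError):
    """A stage failure, naming the stage and the offending input."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r}: {message}")


@dataclass
class PipelineConfig:
    """Validated, default-filled pipeline configuration."""

    wt_n4: list[str]
    mut_n4: list[str]
    wt_t4: list[str]
    mut_t4: list[str]
    out_dir: str
    gtf: str | None = None
    genome_fasta: str | None = None
    motifs: str | None = None
    gene_sets: str | None = None
    score_table: str | None = None
    promoter_halfwidth: int = 3000
    idr_threshold: float = 0.05
    min_overlap_bp: int = 1
    motif_p_threshold: float = 1e-4
    ora_q_threshold: float = 0.05
    has_idr_column: bool = True
    seed: int = 0


def validate_config(source) -> PipelineConfig:
    """Normalise a config mapping or YAML file path into a PipelineConfig.

    Unknown keys are rejected with a closest-match suggestion; every
    type/range violation found is listed in one error.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = dict(source)
    known = set(PipelineConfig.__dataclass_fields__)
    errors: list[str] = []
    for key in raw:
        if key not in known:
            hint = difflib.get_close_matches(key, sorted(known), n=1)
            suffix = f'; did you mean "{hint[0]}"?' if hint else ""
            errors.append(f"unknown key {key!r}{suffix}")
    for cond in CONDITION_KEYS:
        if cond not in raw:
            errors.append(f"missing condition {cond!r} "
                          f"(cell of the 2x2 TCR x IL-2 design)")
    if "out_dir" not in raw:
        errors.append("missing required key 'out_dir'")
    clean = {k: v for k, v in raw.items() if k in known}
    for cond in CONDITION_KEYS:
        if cond in clean:
            paths = clean[cond]
            if isinstance(paths, (str, Path)):
                paths = [str(paths)]
            elif isinstance(paths, Sequence):
                paths = [str(p) for p in paths]
            else:
                errors.append(f"{cond}: expected a path or list of paths")
                continue
            for p in paths:
                if not Path(p).exists():
                    errors.append(f"{cond}: input file not found: {p}")
            clean[cond] = paths
    for key in _OPTIONAL_PATHS:
        value = clean.get(key)
        if value is not None:
            if not Path(value).exists():
                errors.append(f"{key}: input file not found: {value}")
            clean[key] = str(value)
    ranges = {
        "promoter_halfwidth": (int, lambda v: v >= 0, ">= 0"),
        "idr_threshold": ((int, float), lambda v: 0 <= v <= 1, "in [0, 1]"),
        "min_overlap_bp": (int, lambda v: v >= 1, ">= 1"),
        "motif_p_threshold": ((int, float), lambda v: 0 < v <= 1, "in (0, 1]"),
        "ora_q_threshold": ((int, float), lambda v: 0 < v <= 1, "in (0, 1]"),
        "seed": (int, lambda v: True, ""),
        "has_idr_column": (bool, lambda v: True, ""),
    }
    for key, (types, check, desc) in ranges.items():
        if key in clean:
            v = clean[key]
            if not isinstance(v, types) or isinstance(v, bool) != (types is bool):
                errors.append(f"{key}: expected {types}, got {type(v).__name__}")
            elif not check(v):
                errors.append(f"{key}: must be {desc}, got {v}")
    if errors:
        raise ValueError("invalid pipeline configuration:\n  - "
                         + "\n  - ".join(errors))
    merged = {**_DEFAULTS, **clean}
    merged["out_dir"] = str(raw["out_dir"])
    return PipelineConfig(**merged)


def _config_hash(config: PipelineConfig) -> str:
    # identifies the analysis (inputs and parameters), not the output location
    payload = {k: v for k, v in asdict(config).items() if k != "out_dir"}
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def _load_condition(config: PipelineConfig, cond: str) -> list[PeakSet]:
    sets = []
    for i, path in enumerate(getattr(config, cond), 1):
        ivs = read_narrowpeak(path, idr_column=config.has_idr_column)
        sets.append(PeakSet(ivs, label=f"{cond}_rep{i}"))
    return sets


_SAFE = {CATEGORY_TCR: "tcr", CATEGORY_IL2: "il2",
         CATEGORY_SYN_TCR: "syn_tcr_branch", CATEGORY_SYN_IL2: "syn_il2_branch"}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every configured stage; returns the summary dictionary.

    Any stage error aborts with :class:`PipelineError` naming the stage;
    the MANIFEST of completed stages and their partial outputs are
    retained in the output directory.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []
    summary: dict = {
        "metadata": {
            "package_version": __version__,
            "config": asdict(config),
            "config_hash": _config_hash(config),
            "seed": config.seed,
        }
    }

    def finish_stage(name: str) -> None:
        manifest.append(name)
        logger.info("stage %s complete", name)

    def write_manifest() -> None:
        (out / "MANIFEST").write_text(
            "".join(f"{s}\tdone\n" for s in manifest))

    def run_stage(name: str, fn):
        try:
            result = fn()
        except Exception as exc:
            write_manifest()
            raise PipelineError(name, str(exc)) from exc
        finish_stage(name)
        return result

    # -- per-condition preprocessing --------------------------------------
    def load():
        return {cond: _load_condition(config, cond) for cond in CONDITION_KEYS}

    replicates = run_stage("load_peaks", load)
    summary["input_counts"] = {
        cond: [len(ps) for ps in reps] for cond, reps in replicates.items()}

    def idr_stage():
        if not config.has_idr_column:
            return replicates
        return {cond: [idr_filter(ps, config.idr_threshold) for ps in reps]
                for cond, reps in replicates.items()}

    filtered = run_stage("idr_filter", idr_stage)
    summary["idr_filtered_counts"] = {
        cond: [len(ps) for ps in reps] for cond, reps in filtered.items()}

    def reproducible_stage():
        merged = {}
        for cond, reps in filtered.items():
            current = reps[0]
            for nxt in reps[1:]:
                current = replicate_reproducible(current, nxt,
                                                 config.min_overlap_bp)
            merged[cond] = filter_redundant(current, config.min_overlap_bp)
            merged[cond].label = cond
        return merged

    condition_sets = run_stage("replicate_reproducible", reproducible_stage)
    summary["reproducible_counts"] = {c: len(p) for c, p in condition_sets.items()}

    # -- attribution -------------------------------------------------------
    def attribution_stage():
        quad = ConditionQuad.from_dict(condition_sets)
        result = attribute(quad, config.min_overlap_bp)
        for name, ps in [("A", result.A), ("B", result.B),
                         ("X", result.X), ("Y", result.Y)]:
            write_bed(ps, out / f"level1_{name}.bed")
        for cat, ps in result.master_lists().items():
            write_bed(ps, out / f"master_{_SAFE[cat]}.bed")
        return result

    result = run_stage("attribution", attribution_stage)
    summary["attribution_counts"] = dict(result.counts)

    # -- annotation --------------------------------------------------------
    genes = None
    if config.gtf:
        def annotation_stage():
            gene_models = read_gtf_lite(config.gtf)
            index = GeneIndex(gene_models)
            frames = []
            for cat, ps in result.master_lists().items():
                anns = annotate_peaks(ps, index, config.promoter_halfwidth)
                frame = annotation_frame(anns)
                frame.insert(0, "category", cat)
                frames.append(frame)
            import pandas as pd
            pd.concat(frames, ignore_index=True).to_csv(
                out / "annotation.tsv", sep="\t", index=False)
            return index

        genes = run_stage("annotation", annotation_stage)

        def genes_stage():
            per_cat = genes_by_category(result, genes, config.promoter_halfwidth)
            with open(out / "genes_by_category.tsv", "w") as fh:
                fh.write("category\tgene_id\n")
                for cat, ids in per_cat.items():
                    for g in ids:
                        fh.write(f"{cat}\t{g}\n")
            return per_cat

        per_category_genes = run_stage("genes_by_category", genes_stage)
        summary["gene_counts"] = {c: len(g) for c, g in per_category_genes.items()}

        def consistency_stage():
            bc = branch_consistency(result, genes, config.promoter_halfwidth)
            return {
                "jaccard": bc.jaccard,
                "frac_tcr_branch_shared": bc.frac_tcr_branch_shared,
                "frac_il2_branch_shared": bc.frac_il2_branch_shared,
            }

        summary["branch_consistency"] = run_stage("branch_consistency",
                                                  consistency_stage)

        def venn_stage():
            three_way = {c: per_category_genes[c]
                         for c in (CATEGORY_TCR, CATEGORY_IL2, CATEGORY_SYN)}
            counts = venn_counts(three_way)
            serial = {" & ".join(k) if k else "(none)": v
                      for k, v in sorted(counts.items())}
            (out / "gene_venn.json").write_text(
                json.dumps(serial, indent=2, sort_keys=True) + "\n")
            return serial

        summary["gene_venn"] = run_stage("venn_counts", venn_stage)

        summary["category_summary"] = run_stage(
            "category_summary",
            lambda: json.loads(
                category_summary(result, genes, config.promoter_halfwidth)
                .to_json(orient="index")))

        # -- over-representation ------------------------------------------
        if config.gene_sets:
            def ora_stage():
                sets = read_gmt(config.gene_sets)
                universe = [g.gene_id for g in genes.genes]
                out_stats = {}
                for cat in (CATEGORY_TCR, CATEGORY_IL2, CATEGORY_SYN):
                    table = ora(per_category_genes[cat], sets, universe,
                                q_threshold=config.ora_q_threshold)
                    table.to_csv(out / f"ora_{_SAFE.get(cat, 'syn')}.tsv",
                                 sep="\t", index=False)
                    out_stats[cat] = {
                        "n_terms_tested": int(len(table)),
                        "n_significant": int(table.attrs.get("n_significant", 0)),
                    }
                return out_stats

            summary["ora"] = run_stage("ora", ora_stage)

    # -- motifs ------------------------------------------------------------
    if config.genome_fasta and config.motifs:
        def motif_stage():
            genome = read_fasta(config.genome_fasta)
            motif_models = read_motifs(config.motifs)
            all_cond = PeakSet(
                [iv for ps in condition_sets.values() for iv in ps],
                label="all_conditions")
            background = filter_redundant(all_cond, config.min_overlap_bp)
            scan_targets = PeakSet(
                list(background)
                + [iv for ps in result.master_lists().values() for iv in ps],
                label="scan_universe")
            hits = scan(filter_redundant(scan_targets), genome, motif_models,
                        p_threshold=config.motif_p_threshold, merge=False)
            with open(out / "motif_hits.tsv", "w") as fh:
                fh.write("motif_id\tchrom\tstart\tend\tstrand\tscore\tp_value\n")
                for h in hits:
                    fh.write(f"{h.motif_id}\t{h.chrom}\t{h.start}\t{h.end}\t"
                             f"{h.strand}\t{h.score:.4f}\t{h.p_value:.3e}\n")
            matrix = motif_category_enrichment(hits, result.master_lists(),
                                               background)
            matrix.log2_fold.to_csv(out / "motif_enrichment_log2fold.tsv", sep="\t")
            matrix.q.to_csv(out / "motif_enrichment_q.tsv", sep="\t")
            stage_summary = {"n_hits": len(hits),
                             "n_motifs": len(motif_models)}
            try:
                pca = tf_segregation_pca(matrix)
            except ValueError as exc:
                stage_summary["pca"] = f"skipped: {exc}"
            else:
                pca.assignment.to_csv(out / "tf_assignment.tsv", sep="\t",
                                      header=["category"])
                stage_summary["tf_counts_per_category"] = {
                    str(k): int(v) for k, v in pca.category_counts.items()}
            return stage_summary

        summary["motifs"] = run_stage("motifs", motif_stage)

    # -- similarity ----------------------------------------------------------
    if config.score_table:
        def similarity_stage():
            scores = read_score_table(config.score_table)
            sim = pearson_matrix(scores)
            sim.frame.to_csv(out / "similarity_matrix.tsv", sep="\t")
            similarity_edges(sim).to_csv(out / "similarity_edges.tsv",
                                         sep="\t", index=False)
            return {"n_samples": len(sim.sample_ids),
                    "n_peaks": sim.consensus_peak_count}

        summary["similarity"] = run_stage("similarity", similarity_stage)

    def summary_stage():
        (out / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True) + "\n")

    run_stage("summary", summary_stage)
    write_manifest()
    return summary
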