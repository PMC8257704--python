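"""End-to-end orchestration: screen → targets → overlap → dynamics.

``run_all`` chains the four analysis stages on file inputs, writes each
stage's artifacts plus a merged JSON summary, a provenance copy of the
configuration, and a MANIFEST recording which stages completed. A missing
optional input (scores, matrix) downgrades its stage to a logged skip rather
than a failure, so partial datasets still produce the upstream results.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

from . import io as mio
from .mirna_screen import screen_catalogue, summarize_screen
from .overlap_stats import stratified_overlap_report
from .seqcore import DegenerateMotif
from .stage_dynamics import (
    call_regulation,
    summarize_ratios,
    threshold_sensitivity,
)
from .target_annotation import annotate_genes, sites_for_genes

logger = logging.getLogger(__name__)

EXIT_OK = 0
EXIT_VALIDATION = 2
EXIT_STAGE_FAILURE = 3


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    mirnas_path: str | None = None
    utrs_path: str | None = None
    m6a_genes_path: str | None = None
    m6a_peaks_path: str | None = None
    scores_path: str | None = None
    matrix_path: str | None = None
    outdir: str = "m6amir_out"
    relaxed_motif: str = "RRACH"
    stringent_motif: str = "GGACH"
    seed_span: tuple[int, int] = (2, 8)
    focal_mirna: str | None = None  # name in the catalogue; default = first FULL match
    min_site_type: str = "7mer-m8"
    strict_site_overlap: bool = False
    t_variant: str = "pooled"
    reference_stage: str | None = None
    comparison_stage: str | None = None
    fc_threshold: float = 1.5
    pseudocount: float = 0.0
    highlight: str = "down"  # "down" (developmental) or "up" (TAC-style)

    def validate(self) -> None:
        for attr in ("mirnas_path", "utrs_path", "m6a_genes_path", "m6a_peaks_path",
                     "scores_path", "matrix_path"):
            p = getattr(self, attr)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{attr}: no such file {p!r}")
        DegenerateMotif(self.relaxed_motif)
        DegenerateMotif(self.stringent_motif)
        if self.highlight not in ("down", "up"):
            raise ValueError(f"highlight must be 'down' or 'up', got {self.highlight!r}")


def _jsonable(x):
    if isinstance(x, float) and not math.isfinite(x):
        return None if math.isnan(x) else ("inf" if x > 0 else "-inf")
    if dataclasses.is_dataclass(x) and not isinstance(x, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(x).items()}
    if isinstance(x, dict):
        return {str(k): _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple, set)):
        return [_jsonable(v) for v in x]
    return x


def run_all(config: RunConfig) -> tuple[int, Path]:
    """Run every stage the inputs allow; returns (exit status, artifact directory)."""
    try:
        config.validate()
    except (FileNotFoundError, ValueError) as exc:
        logger.error("configuration invalid: %s", exc)
        return EXIT_VALIDATION, Path(config.outdir)

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    summary: dict[str, object] = {}
    relaxed = DegenerateMotif(config.relaxed_motif)
    stringent = DegenerateMotif(config.stringent_motif)

    config_json = json.dumps(_jsonable(dataclasses.asdict(config)), indent=1, sort_keys=True)
    with open(outdir / "config.json", "w") as fh:
        fh.write(config_json + "\n")
    from . import __version__

    logger.info(
        "m6amir %s, config sha256 %s",
        __version__,
        hashlib.sha256(config_json.encode()).hexdigest()[:12],
    )

    annotations = None
    mirnas = []
    focal = None
    try:
        # stage 1: seed-motif screen
        if config.mirnas_path:
            mirnas = mio.read_mirnas(config.mirnas_path, seed_span=config.seed_span)
            results = screen_catalogue(mirnas, relaxed=relaxed, stringent=stringent)
            mio.write_screen_results(outdir / "screen.tsv", results)
            counts = summarize_screen(results)
            summary["screen"] = counts
            manifest["screen"] = "completed"
            logger.info(
                "screen: %d miRNAs, %d FULL, %d PARTIAL, %d NONE",
                counts["n_total"], counts["n_full"], counts["n_partial"], counts["n_none"],
            )
            by_name = {m.name: m for m in mirnas}
            if config.focal_mirna:
                focal = by_name.get(config.focal_mirna)
                if focal is None:
                    raise KeyError(f"focal miRNA {config.focal_mirna!r} not in catalogue")
            else:
                full = [r.mirna_name for r in results if r.match_class == "FULL"]
                focal = by_name[full[0]] if full else mirnas[0]
        else:
            manifest["screen"] = "skipped (no miRNA catalogue)"

        # stage 2: target sites and gene annotation
        if config.utrs_path and focal is not None:
            utrs = mio.read_utrs(config.utrs_path)
            gene_set = (
                mio.read_gene_set(config.m6a_genes_path) if config.m6a_genes_path else set()
            )
            if config.m6a_peaks_path:
                mio.read_bed(config.m6a_peaks_path)  # validated; peaks are provenance-only
            sites = sites_for_genes(utrs, focal, min_site_type=config.min_site_type)
            mio.write_sites_bed(outdir / "sites.bed", sites)
            annotations = annotate_genes(
                utrs,
                focal,
                gene_set,
                motif=stringent,
                strict_site_overlap=config.strict_site_overlap,
                min_site_type=config.min_site_type,
            )
            mio.write_annotations(outdir / "annotations.tsv", annotations)
            summary["targets"] = {
                "focal_mirna": focal.name,
                "n_genes": len(annotations),
                "n_targets": sum(a.is_target for a in annotations),
                "n_m6a_modified_targets": sum(a.m6a_modified_target for a in annotations),
            }
            manifest["targets"] = "completed"
        else:
            manifest["targets"] = "skipped (no UTRs or no focal miRNA)"

        # stage 3: overlap and score comparison
        if annotations is not None and config.scores_path:
            scores = mio.read_scores(config.scores_path)
            report = stratified_overlap_report(annotations, scores, variant=config.t_variant)
            summary["overlap"] = {
                "overlap": _jsonable(report.overlap_summary),
                "comparison": _jsonable(report.comparison),
                "comparison_computable": report.comparison_computable,
                "n_unscored": report.n_unscored,
            }
            report.per_gene.to_csv(outdir / "overlap_per_gene.tsv", sep="\t", index=False)
            manifest["overlap"] = "completed"
        elif annotations is not None:
            logger.warning("no score table supplied; overlap stage skipped")
            manifest["overlap"] = "skipped (no scores)"
        else:
            manifest["overlap"] = "skipped (no annotations)"

        # stage 4: stage dynamics
        if config.matrix_path and config.reference_stage and config.comparison_stage:
            matrix = mio.read_matrix(config.matrix_path, config.reference_stage)
            calls = call_regulation(
                matrix,
                config.comparison_stage,
                fc_threshold=config.fc_threshold,
                pseudocount=config.pseudocount,
            )
            mio.write_calls(outdir / "calls.tsv", calls)
            m6a_status = (
                {a.gene_id: a.m6a_modified_target for a in annotations}
                if annotations is not None
                else {}
            )
            target_ids = (
                {a.gene_id for a in annotations if a.is_target}
                if annotations is not None
                else set(matrix.gene_ids)
            )
            target_calls = [c for c in calls if c.gene_id in target_ids]
            background = [c for c in calls if c.gene_id not in target_ids]
            if target_calls and background:
                summ_t, summ_bg, fold = summarize_ratios(target_calls, background, m6a_status)
                summary["dynamics"] = {
                    "highlight": config.highlight,
                    "targets": _jsonable(summ_t),
                    "background": _jsonable(summ_bg),
                    "target_vs_background_fold": _jsonable(fold),
                }
            else:
                summ_t, _, _ = summarize_ratios(calls, calls, m6a_status)
                summary["dynamics"] = {"highlight": config.highlight, "all_genes": _jsonable(summ_t)}
            sens = threshold_sensitivity(
                matrix, config.comparison_stage, pseudocount=config.pseudocount
            )
            sens.to_csv(outdir / "threshold_sensitivity.tsv", sep="\t", index=False)
            manifest["dynamics"] = "completed"
        else:
            manifest["dynamics"] = "skipped (no matrix or stages unset)"
    except Exception as exc:  # stage failure: keep partial outputs + manifest
        logger.exception("stage failure: %s", exc)
        manifest["error"] = str(exc)
        _write_outputs(outdir, summary, manifest)
        return EXIT_STAGE_FAILURE, outdir

    _write_outputs(outdir, summary, manifest)
    return EXIT_OK, outdir


def _write_outputs(outdir: Path, summary: dict, manifest: dict) -> None:
    with open(outdir / "summary.json", "w") as fh:
        json.dump(_jsonable(summary), fh, indent=1, sort_keys=True)
        fh.write("\n")
    with open(outdir / "MANIFEST.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
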