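"""Composition of scan -> filter -> compare, plus the quantification runners.

Each stage error is wrapped in :class:`PipelineError` carrying the stage
name; partially written report files are removed on failure so a report
directory is either complete (with a manifest) or absent.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Sequence

from Bio import SeqIO

from . import __version__
from .chromatin_filter import (
    ChromatinConfig,
    active_chromatin_filter,
    encode_evidence_filter,
    read_bed_track,
    surviving_hits,
)
from .motif_model import read_jaspar, pfm_to_pwm
from .promoter_compare import genes_with_tf, tf_set, venn_partition
from .promoter_scan import (
    extract_promoter,
    read_anchors,
    scan_promoter,
    write_hits_bed,
    write_hits_tsv,
)
from .quantification import (
    classify_cell,
    correlate_profiles,
    luciferase_fold,
    percent_tubular,
    profiles_to_frame,
    read_ct_table,
    read_luminescence_table,
    read_morphology_table,
    relative_expression,
)

logger = logging.getLogger("cisreg")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    genome: str
    anchors: str
    motifs: str
    histone_track: str
    cluster_track: str
    outdir: str
    window: int = 10_000
    threshold: float = 0.89
    chromatin: ChromatinConfig = field(default_factory=ChromatinConfig)
    seed: int = 0

    def to_json_obj(self) -> dict:
        obj = asdict(self)
        obj["version"] = __version__
        return obj


def load_genome(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, str(exc)) from exc
        return wrapped
    return deco


def run_promoter_pipeline(cfg: RunConfig) -> dict[str, Path]:
    """Run the full promoter analysis and write the report bundle.

    Outputs: ``hits.tsv`` (every above-threshold hit with filter flags),
    ``hits.bed``, ``surviving.tsv``, ``tf_sets.json``, ``venn.json`` and
    ``venn_counts.tsv`` (for 2-3 genes), and ``run_log.json`` with
    per-stage counts plus the serialized config; ``manifest.json`` lists
    everything written.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(name: str, writer) -> Path:
        path = outdir / name
        with open(path, "w") as fh:
            writer(fh)
        written.append(path)
        return path

    try:
        pfms = _stage("load_motifs")(read_jaspar)(open(cfg.motifs))
        if not pfms:
            raise PipelineError("load_motifs", f"no motifs loaded from {cfg.motifs}")
        pwms = [pfm_to_pwm(p) for p in pfms]
        genome = _stage("load_genome")(load_genome)(cfg.genome)
        anchors = _stage("load_anchors")(read_anchors)(cfg.anchors)
        histone = _stage("load_tracks")(read_bed_track)(cfg.histone_track, "histone")
        clusters = _stage("load_tracks")(read_bed_track)(cfg.cluster_track, "tf_cluster")

        counts: dict[str, dict[str, int]] = {}
        all_hits = []
        per_gene_surviving: dict[str, list] = {}
        for anchor in anchors:
            promoter = _stage("extract_promoter")(extract_promoter)(
                genome, anchor, cfg.window
            )
            hits = _stage("scan")(scan_promoter)(pwms, promoter, cfg.threshold)
            hits = _stage("chromatin_filter")(active_chromatin_filter)(
                hits, histone, cfg.chromatin
            )
            hits = _stage("evidence_filter")(encode_evidence_filter)(
                hits, clusters, cfg.chromatin
            )
            survivors = surviving_hits(hits)
            n_chromatin = sum(1 for h in hits if h.chromatin_active == "pass")
            counts[anchor.gene_id] = {
                "all_hits": len(hits),
                "chromatin_pass": n_chromatin,
                "surviving": len(survivors),
            }
            logger.info(
                "%s: %d hits, %d chromatin-active, %d surviving",
                anchor.gene_id, len(hits), n_chromatin, len(survivors),
            )
            all_hits.extend(hits)
            per_gene_surviving[anchor.gene_id] = survivors

        emit("hits.tsv", lambda fh: write_hits_tsv(all_hits, fh))
        emit("hits.bed", lambda fh: write_hits_bed(all_hits, fh))
        flat_surviving = [h for hs in per_gene_surviving.values() for h in hs]
        emit("surviving.tsv", lambda fh: write_hits_tsv(flat_surviving, fh))

        sets = [tf_set(hs) if hs else tf_set([]) for hs in per_gene_surviving.values()]
        # tf_set of an empty list loses the gene id; rebuild it explicitly
        from .promoter_compare import TFBindingSet

        sets = [
            s if s.gene_id else TFBindingSet(gene_id=g, tfs=frozenset(), best_hits={})
            for s, g in zip(sets, per_gene_surviving)
        ]
        tf_sets_obj = {
            s.gene_id: {
                tf: {
                    "local_offset": s.best_hits[tf].local_offset,
                    "relative_score": s.best_hits[tf].relative_score,
                    "efficiency": s.best_hits[tf].efficiency,
                }
                for tf in sorted(s.tfs)
            }
            for s in sets
        }
        emit("tf_sets.json", lambda fh: json.dump(tf_sets_obj, fh, indent=2))

        if 2 <= len(sets) <= 3:
            part = _stage("compare")(venn_partition)(sets)
            emit("venn.json", lambda fh: json.dump(part.to_json_obj(), fh, indent=2))
            emit("venn_counts.tsv", lambda fh: fh.writelines(
                f"{region}\t{n}\n" for region, n in part.counts().items()
            ))

        run_log = {"config": cfg.to_json_obj(), "counts": counts}
        emit("run_log.json", lambda fh: json.dump(run_log, fh, indent=2))
        emit("manifest.json", lambda fh: json.dump(
            sorted(p.name for p in written), fh, indent=2
        ))
        return {p.name: p for p in written}
    except PipelineError:
        for path in written:
            path.unlink(missing_ok=True)
        raise


def run_quantification(
    outdir: str | Path,
    ct_table: str | None = None,
    reference_gene: str = "18S",
    calibrator_time: float | None = None,
    morphology_table: str | None = None,
    luminescence_table: str | None = None,
    correlation_threshold: float = 0.7,
) -> dict[str, Path]:
    """Run whichever quantification inputs are provided; write TSV/JSON reports."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        morph_course: dict[float, float] | None = None
        if morphology_table is not None:
            records = _stage("morphology")(read_morphology_table)(morphology_table)
            by_condition: dict[str, list] = {}
            for r in records:
                by_condition.setdefault(r.condition, []).append(r)
            rows = {
                cond: {
                    "percent_tubular": percent_tubular(rs),
                    "n_cells": len(rs),
                    "mean_peroxisome_count": sum(
                        classify_cell(r)[1] for r in rs
                    ) / len(rs),
                }
                for cond, rs in sorted(by_condition.items())
            }
            path = outdir / "morphology.json"
            path.write_text(json.dumps(rows, indent=2))
            written.append(path)
            try:  # conditions named by numeric time allow correlation pairing
                morph_course = {float(c): v["percent_tubular"] for c, v in rows.items()}
            except ValueError:
                morph_course = None

        if ct_table is not None:
            table = _stage("qpcr")(read_ct_table)(ct_table)
            profiles = _stage("qpcr")(relative_expression)(
                table, reference_gene, calibrator_time
            )
            frame = profiles_to_frame(profiles)
            path = outdir / "expression_profiles.tsv"
            frame.to_csv(path, sep="\t", index=False)
            written.append(path)
            if morph_course:
                report = {}
                for gene, profile in sorted(profiles.items()):
                    try:
                        r, label = correlate_profiles(
                            profile, morph_course, correlation_threshold
                        )
                    except ValueError as exc:
                        report[gene] = {"error": str(exc)}
                        continue
                    report[gene] = {"pearson_r": None if r != r else r,
                                    "classification": label}
                path = outdir / "correlation.json"
                path.write_text(json.dumps(report, indent=2))
                written.append(path)

        if luminescence_table is not None:
            records = _stage("luciferase")(read_luminescence_table)(luminescence_table)
            folds = _stage("luciferase")(luciferase_fold)(records)
            path = outdir / "luciferase_folds.tsv"
            with open(path, "w") as fh:
                fh.write("construct\tfold\n")
                for construct, fold in sorted(folds.items()):
                    fh.write(f"{construct}\t{fold:.6f}\n")
            written.append(path)

        path = outdir / "manifest.json"
        path.write_text(json.dumps(sorted(p.name for p in written), indent=2))
        written.append(path)
        return {p.name: p for p in written}
    except PipelineError:
        for path in written:
            path.unlink(missing_ok=True)
        raise
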