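"""Orchestrate the full analysis from a single declarative config.

Stage order: replicate consensus -> reach extension -> landscape
co-localization (degradation map, active/repressive marks) -> feature
distribution and TSS profile -> TSS-proximal target genes -> co-factor
target overlap -> expression shift tests (raw and BH-adjusted p) -> motif
enrichment. Stages whose inputs are absent from the config are skipped;
any stage failure aborts with the failing stage named. The effective
config and seed are embedded in the report so a rerun reproduces every
value exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import interval_core as ic
from .colocalization_stats import PermutationConfig, fold_enrichment, mark_association
from .expression_link import bh_adjust, gene_set_shift_test, read_expression_table
from .motif_scan import MotifDef, motif_enrichment
from .reach_extension import ReachParams, extend_intervals
from .tss_annotation import (
    AnnotationParams,
    GeneSet,
    assign_target_genes,
    feature_distribution,
    gene_set_overlap_test,
    read_gene_models,
    tss_profile,
)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "compare_bona_fide_vs_extended"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, carrying the failing stage's name."""


@dataclass
class PipelineConfig:
    genome: str
    peaks_rep1: str
    peaks_rep2: Optional[str] = None
    genes: Optional[str] = None
    fasta: Optional[str] = None
    expression: Optional[str] = None
    degradation: Optional[str] = None
    mark_pos: Optional[str] = None
    mark_neg: Optional[str] = None
    cofactor: Optional[str] = None
    gene_sets: dict = field(default_factory=dict)  # name -> path (one id/line)
    consensus_mode: str = "either-anchored-on-A"
    reach: ReachParams = field(default_factory=ReachParams)
    annotation: AnnotationParams = field(default_factory=AnnotationParams)
    seed: int = 0
    n_perm: int = 1000
    motif: str = "CACGTG"
    outdir: Optional[str] = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "reach" in raw and isinstance(raw["reach"], dict):
            raw["reach"] = ReachParams(**raw["reach"])
        if "annotation" in raw and isinstance(raw["annotation"], dict):
            raw["annotation"] = AnnotationParams(**raw["annotation"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage '{name}': {exc}") from exc

        return wrapper

    return deco


def _read_gene_set(name: str, path) -> GeneSet:
    with open(path) as fh:
        ids = [line.strip() for line in fh if line.strip()]
    return GeneSet.from_iterable(name, ids)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all configured stages; returns the serializable report."""
    report: dict = {"config": _json_safe(config.to_dict()), "stages": []}
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    genome = _stage("genome")(ic.read_chrom_sizes)(config.genome)
    rep1 = _stage("peaks")(ic.read_bed)(config.peaks_rep1, genome)
    report["stages"].append("peaks")
    logger.info("replicate 1: %d peaks", len(rep1))

    if config.peaks_rep2:
        rep2 = _stage("consensus")(ic.read_bed)(config.peaks_rep2, genome)
        peaks = _stage("consensus")(ic.consensus)(rep1, rep2, config.consensus_mode)
        report["stages"].append("consensus")
    else:
        peaks = rep1
    report["consensus_peak_count"] = len(peaks)

    flank = int(config.reach.flank_bp)
    regions = _stage("extend")(extend_intervals)(peaks, flank, genome, True)
    report["stages"].append("extend")
    report["flank_bp"] = flank
    report["extended_region_count"] = len(regions)
    report["extended_region_bp"] = regions.total_bp
    if outdir:
        ic.write_bed(regions, outdir / "extended.bed")

    pconf = PermutationConfig(seed=config.seed, n_perm=config.n_perm)
    if config.degradation:
        deg = _stage("degradation")(ic.read_bed)(config.degradation, genome)
        ov = ic.overlap_stats(regions, deg)
        ov_peaks = ic.overlap_stats(peaks, deg)
        enr = _stage("degradation")(fold_enrichment)(regions, deg, genome, pconf)
        report["degradation"] = {
            "overlap": ov.to_dict(),
            "peak_overlap": ov_peaks.to_dict(),
            "enrichment": enr.to_dict(),
        }
        report["stages"].append("degradation")

    if config.mark_pos and config.mark_neg:
        pos = _stage("marks")(ic.read_bed)(config.mark_pos, genome)
        neg = _stage("marks")(ic.read_bed)(config.mark_neg, genome)
        assoc = _stage("marks")(mark_association)(regions, pos, neg, genome, pconf)
        report["marks"] = assoc.to_dict()
        report["stages"].append("marks")

    targets: Optional[GeneSet] = None
    genes = None
    if config.genes:
        genes = _stage("annotation")(read_gene_models)(config.genes, genome)
        fd = _stage("annotation")(feature_distribution)(
            peaks, genes, genome, config.annotation
        )
        prof = _stage("annotation")(tss_profile)(peaks, genes, config.annotation)
        targets, assignment = _stage("annotation")(assign_target_genes)(
            peaks, genes, config.annotation
        )
        report["feature_distribution"] = fd.to_dict()
        report["tss_profile"] = {
            "bin_center": prof.bin_center.tolist(),
            "density": prof.density.tolist(),
            "n_in_window": prof.n_in_window,
        }
        report["target_genes"] = sorted(targets.gene_ids)
        report["stages"].append("annotation")
        if outdir:
            assignment.to_csv(outdir / "targets.tsv", sep="\t", index=False)
            prof.to_frame().to_csv(outdir / "profile.tsv", sep="\t", index=False)

    if config.cofactor and genes is not None and targets is not None and len(targets):
        cof = _stage("cofactor")(ic.read_bed)(config.cofactor, genome)
        cof_targets, _ = _stage("cofactor")(assign_target_genes)(
            cof, genes, config.annotation
        )
        if len(cof_targets):
            universe = GeneSet.from_iterable("universe", genes["gene_id"])
            cont, frac = _stage("cofactor")(gene_set_overlap_test)(
                targets, cof_targets, universe
            )
            report["cofactor_overlap"] = {
                "contingency": cont.to_dict(),
                "fraction_of_targets": frac,
            }
            report["stages"].append("cofactor")

    if config.expression and targets is not None and len(targets):
        expr = _stage("shift-tests")(read_expression_table)(config.expression)
        tests = {"targets": _stage("shift-tests")(gene_set_shift_test)(expr, targets)}
        for name, path in config.gene_sets.items():
            gs = _read_gene_set(name, path)
            tests[name] = _stage("shift-tests")(gene_set_shift_test)(expr, gs)
        raw_p = [t.test.p_value for t in tests.values()]
        adj = bh_adjust(raw_p)
        report["shift_tests"] = {
            name: {**t.to_dict(), "p_adjusted_bh": float(adj[i])}
            for i, (name, t) in enumerate(tests.items())
        }
        report["stages"].append("shift-tests")
        if outdir:
            pd.DataFrame(
                [
                    {
                        "gene_set": name,
                        "p_raw": t.test.p_value,
                        "p_adjusted_bh": float(adj[i]),
                        "median_targets": t.median_targets,
                        "median_background": t.median_background,
                    }
                    for i, (name, t) in enumerate(tests.items())
                ]
            ).to_csv(outdir / "shift.tsv", sep="\t", index=False)

    if config.fasta:
        import pyfaidx

        fa = _stage("motif")(pyfaidx.Fasta)(config.fasta)
        enr = _stage("motif")(motif_enrichment)(
            peaks, fa, MotifDef(consensus=config.motif), genome, pconf
        )
        report["motif_enrichment"] = enr.to_dict()
        report["stages"].append("motif")
        if outdir:
            with open(outdir / "motif.json", "w") as fh:
                json.dump(enr.to_dict(), fh, indent=2)

    if outdir:
        with open(outdir / "report.json", "w") as fh:
            json.dump(_json_safe(report), fh, indent=2)
    return report


def compare_bona_fide_vs_extended(
    peaks_rep1: ic.IntervalSet,
    peaks_rep2: ic.IntervalSet,
    cofactor: ic.IntervalSet,
    genes: pd.DataFrame,
    expr: pd.DataFrame,
    genome: ic.GenomeDef,
    reach: Optional[ReachParams] = None,
    annotation: Optional[AnnotationParams] = None,
    consensus_mode: str = "either-anchored-on-A",
    alternative: str = "two-sided",
) -> dict:
    """Shift tests from two target definitions, reported side by side.

    (i) bona fide: replicate-consensus peaks that also carry the co-factor
    (peak-level overlap), TSS-assigned; (ii) extended: reach-extended
    merged regions, TSS-assigned. The bona fide definition is the sharper
    one when only promoter-proximal co-bound genes carry a true shift.
    """
    if len(cofactor) == 0:
        raise PipelineError("stage 'bona-fide': empty co-factor peak set")
    reach = reach or ReachParams()
    annotation = annotation or AnnotationParams()
    cons = ic.consensus(peaks_rep1, peaks_rep2, consensus_mode)
    bona = ic.consensus(cons, cofactor, "either-anchored-on-A")
    if len(bona) == 0:
        raise PipelineError("stage 'bona-fide': no consensus peaks carry the co-factor")
    t_bona, _ = assign_target_genes(bona, genes, annotation)
    regions = extend_intervals(cons, int(reach.flank_bp), genome, True)
    t_ext, _ = assign_target_genes(regions, genes, annotation)
    out = {}
    for label, ts in (("bona_fide", t_bona), ("extended", t_ext)):
        res = gene_set_shift_test(expr, ts, alternative=alternative)
        out[label] = {**res.to_dict(), "n_target_genes": len(ts)}
    return out


def _json_safe(obj):
    if isinstance(obj, dict):
        return {k: _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_safe(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _json_safe(dataclasses.asdict(obj))
    return obj
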