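"""End-to-end orchestration: (simulate | ingest) -> normalize -> DE ->
cluster -> enrich -> GS -> select -> stability -> stage, from one config.

Every stage writes its result table as TSV into the run directory and a
``manifest.json`` records the exact thresholds, seed and per-stage
dimensions, so a run can be reproduced bit-for-bit from its manifest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clustering import cut_to_k, hierarchical_cluster
from .data_model import (
    CountMatrix,
    DataValidationError,
    ExpressionMatrix,
    read_annotation,
    read_counts,
    write_cq,
)
from .diffexp import all_pairwise_contrasts, filter_expressed, stage_overlap_sets
from .enrichment import enrich_bins
from .gene_significance import gene_significance
from .normalize import log2p, to_cpm, to_rpkm, zscore_rows
from .qpcr_staging import classify_stages, normalize_to_references, relative_abundance
from .selection import select_housekeepers, select_markers
from .stability import rank_stability
from .synthetic_data import SimulationConfig, simulate_counts, simulate_cq

log = logging.getLogger("haustostage")


@dataclass
class PipelineConfig:
    """All tunable thresholds of the discovery chain, with the defaults the
    analysis is built around."""

    counts_path: str | None = None
    sheet_path: str | None = None
    annotation_path: str | None = None
    simulate: bool = True
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    alpha: float = 0.05
    lfc: float = 1.5
    gs_min: float = 0.7
    gs_alpha: float = 0.05
    min_mean_rpkm: float = 2.0
    min_log2rpkm: float = 5.0
    low_var_quantile: float = 0.10
    k_clusters: int = 12
    z_min: float = 1.0
    relax_stage: str | None = "ATT"
    markers_per_stage_panel: int = 3
    n_reference_genes: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("alpha", "gs_alpha", "low_var_quantile"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise DataValidationError(f"{name}={v} outside (0, 1]")
        if not -1 <= self.gs_min <= 1:
            raise DataValidationError("gs_min must lie in [-1, 1]")
        if self.lfc < 0 or self.z_min < 0 or self.min_mean_rpkm < 0:
            raise DataValidationError("thresholds must be non-negative")
        if self.k_clusters < 1:
            raise DataValidationError("k_clusters must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.pop("schema_version", None)
        sim = raw.pop("sim", None)
        cfg = cls(**raw)
        if sim:
            if "n_markers_per_stage" in sim:
                sim["n_markers_per_stage"] = dict(sim["n_markers_per_stage"])
            if "library_size_range" in sim:
                sim["library_size_range"] = tuple(sim["library_size_range"])
            if "length_range_bp" in sim:
                sim["length_range_bp"] = tuple(sim["length_range_bp"])
            cfg.sim = SimulationConfig(**sim)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["schema_version"] = 1
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run the full chain; returns the manifest dict (also written as JSON)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "config": _jsonable(asdict(config)), "stages": {}}
    failed_marker = out / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()

    try:
        _run(config, out, manifest)
    except Exception as exc:  # partial outputs retained with a FAILED marker
        stage = manifest.get("current_stage", "unknown")
        failed_marker.write_text(f"stage: {stage}\nerror: {exc}\n")
        raise

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _run(config: PipelineConfig, out: Path, manifest: dict) -> None:
    def stage(name: str):
        manifest["current_stage"] = name
        log.info("stage %s", name)

    stage("ingest")
    if config.simulate:
        sim = SimulationConfig(**{**asdict(config.sim), "seed": config.seed})
        counts, truth = simulate_counts(sim)
        pd.Series(truth, name="role").rename_axis("transcript_id").to_csv(
            out / "truth.tsv", sep="\t"
        )
    else:
        if not config.counts_path or not config.sheet_path:
            raise DataValidationError("counts_path and sheet_path required when not simulating")
        counts, truth = read_counts(config.counts_path, config.sheet_path), None
    _write_counts_like(counts, out / "counts.tsv", out / "samples.tsv")
    manifest["stages"]["ingest"] = {
        "transcripts": counts.counts.shape[0],
        "samples": counts.counts.shape[1],
    }

    stage("filter")
    kept = filter_expressed(counts)
    manifest["stages"]["filter"] = {"transcripts_retained": kept.counts.shape[0]}

    stage("diffexp")
    contrasts = all_pairwise_contrasts(kept, alpha=config.alpha, lfc=config.lfc)
    for (a, b), res in contrasts.items():
        res.table.rename_axis("transcript_id").to_csv(out / f"de_{a}_vs_{b}.tsv", sep="\t")
    ref_contrasts = {
        b: res for (a, b), res in contrasts.items() if a == "niS"
    }
    if len(ref_contrasts) == 3:
        regions = stage_overlap_sets(ref_contrasts)
        pd.DataFrame(
            [{"region": k, "n": len(v)} for k, v in regions.items()]
        ).to_csv(out / "venn_regions.tsv", sep="\t", index=False)
    manifest["stages"]["diffexp"] = {
        "contrasts": len(contrasts),
        "significant": {f"{a}_vs_{b}": int(len(r.significant)) for (a, b), r in contrasts.items()},
        "common_dispersion": next(iter(contrasts.values())).dispersion.common_phi,
    }

    stage("cluster")
    sig_any = sorted(set().union(*(set(r.significant) for r in contrasts.values())))
    manifest["stages"]["cluster"] = {"deg_transcripts": len(sig_any)}
    if len(sig_any) >= max(2, config.k_clusters):
        z = zscore_rows(log2p(to_cpm(kept), 1.0))
        z_deg = ExpressionMatrix(
            values=z.values.loc[sig_any], measure="zscore", samples=kept.samples
        )
        dendro = hierarchical_cluster(z_deg, axis="rows")
        assignment = cut_to_k(dendro, config.k_clusters)
        assignment.assignment.rename("cluster").rename_axis("transcript_id").to_csv(
            out / "clusters.tsv", sep="\t"
        )
        (out / "dendrogram_rows.nwk").write_text(dendro.to_newick())
        manifest["stages"]["cluster"]["k"] = assignment.k

    stage("gene_significance")
    gs = gene_significance(
        kept, min_mean_rpkm=config.min_mean_rpkm, gs_min=config.gs_min, alpha=config.gs_alpha
    )
    gs.gs.round(4).rename_axis("transcript_id").to_csv(out / "gs.tsv", sep="\t")
    manifest["stages"]["gene_significance"] = {"transcripts_tested": gs.gs.shape[0]}

    stage("enrichment")
    if config.annotation_path:
        annot = read_annotation(config.annotation_path)
        result = enrich_bins(set(sig_any), set(kept.transcript_ids), annot, alpha=config.alpha)
        result.table.to_csv(out / "enrichment.tsv", sep="\t")
        manifest["stages"]["enrichment"] = {"bins_enriched": int(result.table["enriched"].sum())}

    stage("selection")
    hk = select_housekeepers(
        kept,
        contrasts,
        min_log2rpkm=config.min_log2rpkm,
        low_var_quantile=config.low_var_quantile,
        alpha=config.alpha,
        lfc=config.lfc,
    )
    markers = select_markers(
        kept, contrasts, gs, z_min=config.z_min, relax_stage=config.relax_stage,
        alpha=config.alpha, lfc=config.lfc,
    )
    hk.table.rename_axis("transcript_id").round(4).to_csv(out / "housekeepers.tsv", sep="\t")
    markers.table.round(4).to_csv(out / "markers.tsv", sep="\t")
    manifest["stages"]["selection"] = {
        "housekeepers": len(hk.candidates),
        "markers": {s: len(markers.for_stage(s)) for s in counts.samples.stages_present()},
    }

    stage("qpcr")
    panel = markers.panel(per_stage=config.markers_per_stage_panel)
    references = hk.table.index[: config.n_reference_genes].tolist()
    qpcr_genes = references + [g for genes in panel.values() for g in genes]
    if references and all(panel.values()):
        expr = log2p(to_rpkm(kept.subset_transcripts(qpcr_genes)), 1.0)
        sim_cfg = SimulationConfig(**{**asdict(config.sim), "seed": config.seed})
        cq = simulate_cq(expr, sim_cfg) if config.simulate else None
        if cq is not None:
            write_cq(cq, out / "cq.tsv")
            rq = relative_abundance(cq, efficiency=sim_cfg.efficiency)
            norm = normalize_to_references(rq, references)
            call = classify_stages(norm, panel)
            call.calls.rename("stage").rename_axis("sample_id").to_csv(
                out / "stage_calls.tsv", sep="\t"
            )
            cq_matrix = cq.mean_cq().loc[references]
            ranking = rank_stability(cq_matrix, groups=kept.samples.stages) if len(references) >= 3 else None
            if ranking is not None:
                ranking.table.rename_axis("candidate").to_csv(out / "stability.tsv", sep="\t")
            truth_stages = kept.samples.stages
            correct = int((call.calls == truth_stages.reindex(call.calls.index)).sum())
            manifest["stages"]["qpcr"] = {
                "panel": panel,
                "references": references,
                "correct_stage_calls": correct,
                "samples": int(len(call.calls)),
            }

    manifest.pop("current_stage", None)


def _write_counts_like(cm: CountMatrix, path: Path, sheet_path: Path) -> None:
    out = cm.counts.copy()
    out.insert(0, "length_bp", cm.lengths_bp)
    out.index.name = "transcript_id"
    out.to_csv(path, sep="\t")
    cm.samples.table.to_csv(sheet_path, sep="\t", index=False)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
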