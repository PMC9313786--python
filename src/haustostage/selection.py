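"""Housekeeper and stage-marker candidate definitions as executable filters.

Housekeeper candidates must (1) be expressed (RPKM > 0) in every sample,
(2) have mean log2(RPKM) of at least 5, (3) lie within the lowest 10% of
both the coefficient-of-variation and median-absolute-deviation
distributions of log2(RPKM) over the population passing (1)-(2), and
(4) show no significant fold change (FDR > 0.05 or |log2FC| < 1.5) in any
all-versus-all pairwise stage contrast.

Marker candidates for a stage must (1) be significantly higher in that stage
in every pairwise contrast against the other stages, (2) carry a mean
z-score of at least 1 over the stage's replicates, and (3) pass the gene-
significance thresholds (GS >= 0.7, p.GS <= 0.05) for that stage. A single
stage may be relaxed to require only 2 of its 3 contrasts, mirroring the
transitory attaching stage whose low-abundance markers rarely clear all
three.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import CountMatrix, DataValidationError, validate_stage
from .diffexp import ContrastResult
from .gene_significance import GeneSignificance
from .normalize import log2p, to_cpm, to_rpkm, zscore_rows

DEFAULT_MIN_LOG2RPKM = 5.0
DEFAULT_LOW_VAR_QUANTILE = 0.10
DEFAULT_Z_MIN = 1.0


def _contrast_lookup(
    de: dict[tuple[str, str], ContrastResult]
) -> dict[frozenset, ContrastResult]:
    return {frozenset((r.stage_a, r.stage_b)): r for r in de.values()}


def _require_all_pairs(lookup: dict[frozenset, ContrastResult], stages: list[str]) -> None:
    from itertools import combinations

    for a, b in combinations(stages, 2):
        if frozenset((a, b)) not in lookup:
            raise DataValidationError(f"missing pairwise contrast {a} vs {b}")


@dataclass
class HousekeeperReport:
    """Housekeeper candidates with their stability descriptors."""

    table: pd.DataFrame  # index transcript; mean_log2rpkm, se, cv, mad
    low_var_quantile: float

    @property
    def candidates(self) -> list[str]:
        return list(self.table.index)


@dataclass
class MarkerReport:
    """Marker candidates with stage assignment and supporting statistics."""

    table: pd.DataFrame
    # index transcript; stage, zscore, gs, p_gs, mean_log2rpkm, se, max, min, relaxed

    @property
    def candidates(self) -> list[str]:
        return list(self.table.index)

    def for_stage(self, stage: str) -> list[str]:
        return self.table.index[self.table["stage"] == stage].tolist()

    def panel(self, per_stage: int | None = None) -> dict[str, list[str]]:
        """Stage -> marker gene lists, optionally the top ``per_stage`` by GS."""
        out: dict[str, list[str]] = {}
        for stage, block in self.table.groupby("stage"):
            ordered = block.sort_values("gs", ascending=False).index.tolist()
            out[str(stage)] = ordered[:per_stage] if per_stage else ordered
        return out


def _log2rpkm_stats(counts: CountMatrix) -> pd.DataFrame:
    rpkm = to_rpkm(counts).values
    log2rpkm = np.log2(rpkm + 1.0)  # +1 offset keeps zero-RPKM entries finite
    n = log2rpkm.shape[1]
    mean = log2rpkm.mean(axis=1)
    sd = log2rpkm.std(axis=1, ddof=1)
    mad = (log2rpkm.sub(log2rpkm.median(axis=1), axis=0)).abs().median(axis=1)
    return pd.DataFrame(
        {
            "expressed_everywhere": (rpkm > 0).all(axis=1),
            "mean_log2rpkm": mean,
            "se": sd / np.sqrt(n),
            "cv": sd / mean.abs(),
            "mad": mad,
            "max_log2rpkm": log2rpkm.max(axis=1),
            "min_log2rpkm": log2rpkm.min(axis=1),
        }
    )


def select_housekeepers(
    counts: CountMatrix,
    de: dict[tuple[str, str], ContrastResult],
    min_log2rpkm: float = DEFAULT_MIN_LOG2RPKM,
    low_var_quantile: float = DEFAULT_LOW_VAR_QUANTILE,
    alpha: float = 0.05,
    lfc: float = 1.5,
) -> HousekeeperReport:
    lookup = _contrast_lookup(de)
    _require_all_pairs(lookup, counts.samples.stages_present())
    stats_df = _log2rpkm_stats(counts)

    high = stats_df[
        stats_df["expressed_everywhere"] & (stats_df["mean_log2rpkm"] >= min_log2rpkm)
    ]
    if high.empty:
        raise DataValidationError("no transcripts pass the expression criteria")
    cv_cut = high["cv"].quantile(low_var_quantile)
    mad_cut = high["mad"].quantile(low_var_quantile)
    stable = high[(high["cv"] <= cv_cut) & (high["mad"] <= mad_cut)]

    # criterion 4: null in every pairwise contrast
    keep = []
    for tid in stable.index:
        null_everywhere = True
        for result in lookup.values():
            if tid not in result.table.index:
                null_everywhere = False
                break
            row = result.table.loc[tid]
            if row["FDR"] <= alpha and abs(row["log2FC"]) >= lfc:
                null_everywhere = False
                break
        if null_everywhere:
            keep.append(tid)

    table = stable.loc[keep, ["mean_log2rpkm", "se", "cv", "mad"]].sort_values("cv")
    return HousekeeperReport(table=table, low_var_quantile=low_var_quantile)


def select_markers(
    counts: CountMatrix,
    de: dict[tuple[str, str], ContrastResult],
    gs: GeneSignificance,
    z_min: float = DEFAULT_Z_MIN,
    relax_stage: str | None = None,
    min_significant_when_relaxed: int = 2,
    alpha: float = 0.05,
    lfc: float = 1.5,
) -> MarkerReport:
    """Stage-marker candidates per the three-criteria reductionist filter."""
    sheet = counts.samples
    stages = sheet.stages_present()
    lookup = _contrast_lookup(de)
    _require_all_pairs(lookup, stages)
    if relax_stage is not None:
        validate_stage(relax_stage)

    stats_df = _log2rpkm_stats(counts)
    z = zscore_rows(log2p(to_cpm(counts), 1.0)).values
    stage_cols = {s: sheet.samples_of_stage(s) for s in stages}

    rows = []
    assigned: dict[str, str] = {}
    for stage in stages:
        others = [s for s in stages if s != stage]
        required = (
            min_significant_when_relaxed if stage == relax_stage else len(others)
        )
        # significant *up in this stage* per contrast against each other stage
        up_counts = pd.Series(0, index=counts.counts.index)
        for other in others:
            result = lookup[frozenset((stage, other))]
            tab = result.table
            sig = (tab["FDR"] <= alpha) & (tab["log2FC"].abs() >= lfc)
            if result.stage_b == stage:
                up = sig & (tab["log2FC"] > 0)
            else:
                up = sig & (tab["log2FC"] < 0)
            up_counts = up_counts.add(up.astype(int), fill_value=0)
        crit1 = up_counts >= required
        mean_z = z[stage_cols[stage]].mean(axis=1)
        crit2 = mean_z >= z_min
        crit3 = pd.Series(False, index=counts.counts.index)
        common = gs.passes.index.intersection(counts.counts.index)
        crit3.loc[common] = gs.passes.loc[common, stage].values
        selected = counts.counts.index[crit1 & crit2 & crit3]
        for tid in selected:
            if tid in assigned:
                raise AssertionError(
                    f"transcript {tid} qualifies for both {assigned[tid]} and {stage}; "
                    "the all-pairwise criterion should make this impossible"
                )
            assigned[tid] = stage
            rows.append(
                {
                    "transcript_id": tid,
                    "stage": stage,
                    "zscore": float(mean_z.loc[tid]),
                    "gs": float(gs.gs.loc[tid, stage]),
                    "p_gs": float(gs.p_gs.loc[tid, stage]),
                    "mean_log2rpkm": float(stats_df.loc[tid, "mean_log2rpkm"]),
                    "se": float(stats_df.loc[tid, "se"]),
                    "max_log2rpkm": float(stats_df.loc[tid, "max_log2rpkm"]),
                    "min_log2rpkm": float(stats_df.loc[tid, "min_log2rpkm"]),
                    "relaxed": stage == relax_stage,
                }
            )

    table = (
        pd.DataFrame(
            rows,
            columns=[
                "transcript_id",
                "stage",
                "zscore",
                "gs",
                "p_gs",
                "mean_log2rpkm",
                "se",
                "max_log2rpkm",
                "min_log2rpkm",
                "relaxed",
            ],
        )
        .set_index("transcript_id")
        .sort_values(["stage", "gs"], ascending=[True, False])
    )
    return MarkerReport(table=table)
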