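"""RT-qPCR relative quantification, reference normalization, stage calls.

Technical-replicate Cq values are averaged per gene x sample; each gene's
abundance is expressed relative to its highest-expressing (lowest-Cq)
sample via RQ = efficiency**(Cq_min - Cq). Reference genes provide a
per-sample geometric-mean normalization factor. Stage classification
z-scores the log2 normalized abundances per gene across samples and calls,
for each sample, the stage whose marker set carries the highest mean
z-score; a complete-linkage Euclidean dendrogram of the samples is emitted
alongside for the heatmap-style view.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clustering import Dendrogram, hierarchical_cluster
from .data_model import (
    CqTable,
    DataValidationError,
    ExpressionMatrix,
    SampleSheet,
    stage_order_key,
)
from .normalize import zscore_rows


@dataclass
class RelativeAbundance:
    """Gene x sample relative quantities in (0, 1], max per gene = 1."""

    values: pd.DataFrame
    efficiency: float


@dataclass
class StageCall:
    calls: pd.Series  # sample -> stage
    mean_z: pd.DataFrame  # sample x stage mean marker z-score
    ambiguous: pd.Series  # ties resolved by developmental order, flagged
    dendrogram: Dendrogram


def relative_abundance(cq: CqTable, efficiency: float = 2.0) -> RelativeAbundance:
    """Per gene: RQ_s = efficiency**(Cq_min - Cq_s) after technical averaging."""
    if not 1 < efficiency <= 2:
        raise DataValidationError("amplification efficiency must lie in (1, 2]")
    mean_cq = cq.mean_cq()
    all_missing = mean_cq.isna().all(axis=1)
    if all_missing.any():
        raise DataValidationError(
            f"gene(s) measured in no sample: {mean_cq.index[all_missing].tolist()}"
        )
    cq_min = mean_cq.min(axis=1)
    rq = efficiency ** (cq_min.values[:, None] - mean_cq.values)
    return RelativeAbundance(
        values=pd.DataFrame(rq, index=mean_cq.index, columns=mean_cq.columns),
        efficiency=efficiency,
    )


def normalize_to_references(
    rq: RelativeAbundance, reference_genes: list[str]
) -> RelativeAbundance:
    """Divide each sample's target RQs by the geometric mean of its reference
    RQs; references are removed from the output."""
    if not reference_genes:
        raise DataValidationError("need at least one reference gene")
    missing = [g for g in reference_genes if g not in rq.values.index]
    if missing:
        raise DataValidationError(f"reference gene(s) absent: {missing}")
    refs = rq.values.loc[reference_genes]
    if refs.isna().any().any():
        bad = refs.columns[refs.isna().any(axis=0)].tolist()
        raise DataValidationError(f"reference gene not measured in sample(s): {bad}")
    factor = np.exp(np.log(refs).mean(axis=0))
    targets = rq.values.drop(index=reference_genes)
    return RelativeAbundance(values=targets.div(factor, axis=1), efficiency=rq.efficiency)


def classify_stages(
    norm_rq: RelativeAbundance,
    marker_panel: dict[str, list[str]],
    training_profiles: pd.DataFrame | None = None,
) -> StageCall:
    """Assign each sample the stage whose markers have the highest mean z-score.

    ``marker_panel`` maps stages to marker gene lists; every panel gene must
    be measured in every sample. If ``training_profiles`` (stage x gene
    centroid z-scores) is given, Euclidean distances to the centroids are
    used instead of the raw mean-z rule.
    """
    values = norm_rq.values
    if values.shape[1] < 2:
        raise DataValidationError("classification needs at least 2 samples")
    panel_genes = [g for genes in marker_panel.values() for g in genes]
    missing = [g for g in panel_genes if g not in values.index]
    if missing:
        raise DataValidationError(f"panel gene(s) not measured: {missing}")
    if values.loc[panel_genes].isna().any().any():
        raise DataValidationError("panel contains unmeasured cells")

    log_expr = np.log2(values.loc[panel_genes])
    sheet = _pseudo_sheet(values.columns)
    z = zscore_rows(
        ExpressionMatrix(values=log_expr, measure="log2RPKM", samples=sheet)
    ).values

    stages = sorted(marker_panel, key=stage_order_key)
    if training_profiles is not None:
        dist = pd.DataFrame(
            {
                s: np.sqrt(
                    ((z.loc[marker_panel[s]].T - training_profiles.loc[s, marker_panel[s]]) ** 2).sum(axis=1)
                )
                for s in stages
            }
        )
        score = -dist
    else:
        score = pd.DataFrame({s: z.loc[marker_panel[s]].mean(axis=0) for s in stages})

    calls, ambiguous = {}, {}
    for sample in score.index:
        row = score.loc[sample]
        best = row.max()
        tied = [s for s in stages if np.isclose(row[s], best)]
        calls[sample] = min(tied, key=stage_order_key)
        ambiguous[sample] = len(tied) > 1
        if ambiguous[sample]:
            warnings.warn(f"ambiguous stage call for sample {sample}: tie among {tied}")

    dendro = hierarchical_cluster(
        ExpressionMatrix(values=z, measure="zscore", samples=sheet), axis="columns"
    )
    return StageCall(
        calls=pd.Series(calls).reindex(values.columns),
        mean_z=score,
        ambiguous=pd.Series(ambiguous).reindex(values.columns),
        dendrogram=dendro,
    )


def _pseudo_sheet(sample_ids) -> SampleSheet:
    """Minimal sheet for samples whose stages are yet unknown (the matrix
    transforms only need the sample axis)."""
    return SampleSheet(
        pd.DataFrame(
            {
                "sample_id": list(sample_ids),
                "stage": "niS",
                "replicate": range(1, len(sample_ids) + 1),
                "system": "host-induced",
            }
        )
    )
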