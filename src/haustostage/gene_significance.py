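"""Gene significance: correlation of expression with stage indicator patterns.

For each transcript and each stage, GS is the Pearson correlation between
the transcript's expression across samples and a binary indicator vector (1
for samples of the stage, 0 otherwise); p.GS is the exact two-sided p-value
from the t-transform t = r * sqrt((n-2)/(1-r^2)) on n-2 degrees of freedom.
Transcripts of interest carry GS >= 0.7 and p.GS <= 0.05 (inclusive), after
discarding low-abundance transcripts below a mean-RPKM floor of 2.

Correlations are computed on log2(RPKM + 1) by default; GS is invariant to
positive affine rescaling of the expression row, so the choice of log base
or offset shifts nothing but the linearity of the response.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import (
    CountMatrix,
    DataValidationError,
    ExpressionMatrix,
    SampleSheet,
    validate_stage,
)
from .normalize import log2p, to_rpkm

DEFAULT_MIN_MEAN_RPKM = 2.0
DEFAULT_GS_MIN = 0.7
DEFAULT_GS_ALPHA = 0.05


def stage_indicator(sheet: SampleSheet, stage: str) -> pd.Series:
    """Binary per-sample vector: 1 for samples of ``stage``, 0 otherwise."""
    validate_stage(stage)
    if stage not in sheet.stages_present():
        raise DataValidationError(f"stage {stage!r} absent from sample sheet")
    return (sheet.stages == stage).astype(float)


def gs_pvalue(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p-value of a Pearson correlation via the exact t-transform."""
    r = np.clip(np.asarray(r, dtype=float), -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isclose(np.abs(r), 1.0)] = 0.0
    return p


@dataclass
class GeneSignificance:
    """Per transcript x stage GS, p.GS and pass flags.

    gs / p_gs: DataFrames indexed by transcript, one column per stage.
    passes: boolean DataFrame (GS >= gs_min and p.GS <= alpha).
    undefined: boolean Series flagging constant expression rows, which are
    reported as not passing rather than silently NaN.
    """

    gs: pd.DataFrame
    p_gs: pd.DataFrame
    passes: pd.DataFrame
    undefined: pd.Series
    gs_min: float
    alpha: float

    def passing(self, stage: str) -> pd.Index:
        return self.passes.index[self.passes[stage]]

    def best_stage(self) -> pd.Series:
        return self.gs.idxmax(axis=1)


def gene_significance(
    counts: CountMatrix,
    min_mean_rpkm: float = DEFAULT_MIN_MEAN_RPKM,
    gs_min: float = DEFAULT_GS_MIN,
    alpha: float = DEFAULT_GS_ALPHA,
    expression: ExpressionMatrix | None = None,
) -> GeneSignificance:
    """GS and p.GS for every expressed transcript against every stage.

    ``expression`` overrides the default log2(RPKM+1) correlation input; it
    must share the count matrix's axes.
    """
    sheet = counts.samples
    n = len(sheet.sample_ids)
    if n < 3:
        raise DataValidationError("gene significance needs >=3 samples")
    rpkm = to_rpkm(counts)
    keep = rpkm.values.mean(axis=1) >= min_mean_rpkm
    kept_ids = rpkm.values.index[keep]
    if expression is None:
        expr_values = log2p(rpkm, 1.0).values.loc[kept_ids]
    else:
        expr_values = expression.values.loc[kept_ids]

    x = expr_values.values.astype(float)
    x_centered = x - x.mean(axis=1, keepdims=True)
    x_ss = np.sqrt((x_centered**2).sum(axis=1))
    undefined = x_ss == 0

    gs_cols, p_cols = {}, {}
    for stage in sheet.stages_present():
        ind = stage_indicator(sheet, stage).values
        ind_centered = ind - ind.mean()
        ind_ss = np.sqrt((ind_centered**2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (x_centered @ ind_centered) / (x_ss * ind_ss)
        r = np.where(undefined, np.nan, r)
        gs_cols[stage] = r
        p = gs_pvalue(np.nan_to_num(r), n)
        p_cols[stage] = np.where(undefined, np.nan, p)

    gs = pd.DataFrame(gs_cols, index=kept_ids)
    p_gs = pd.DataFrame(p_cols, index=kept_ids)
    passes = (gs >= gs_min) & (p_gs <= alpha)
    passes[gs.isna()] = False
    return GeneSignificance(
        gs=gs,
        p_gs=p_gs,
        passes=passes.astype(bool),
        undefined=pd.Series(undefined, index=kept_ids),
        gs_min=gs_min,
        alpha=alpha,
    )
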