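"""Reference-gene stability: geNorm, NormFinder, BestKeeper, rank integration.

Each method consumes the scale its original publication defines:

* geNorm works on relative quantities (e.g. 2**-dCq). The stability M of a
  candidate is the mean, over all other candidates, of the standard
  deviation of the pairwise log2 ratio across samples; candidates are
  excluded stepwise (highest M first, recomputing after each exclusion)
  until two remain, which share rank 1. Pairwise variations V(n/n+1)
  compare normalization factors built from the n vs n+1 most stable genes.
* NormFinder works on log-scale quantities and combines candidate-specific
  inter-group bias with intra-group variance into a single stability value
  SV (lower = more stable).
* BestKeeper works directly on Cq values: each candidate is correlated
  (Pearson) against the BestKeeper index, the per-sample arithmetic mean Cq
  over candidates (the geometric mean of the underlying quantities).

Per-method rankings use competition ("min") ranking - tied candidates share
the smaller rank and the next rank is skipped - and are integrated as the
geometric mean of the three ranks (GM), final ordering by ascending GM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import DataValidationError


# ---------------------------------------------------------------------------
# geNorm
# ---------------------------------------------------------------------------

@dataclass
class GenormResult:
    m_values: pd.Series  # initial M per candidate (all candidates included)
    exclusion_order: list[str]  # least stable first; final pair last two
    ranks: pd.Series  # competition ranks; final pair shares rank 1
    pairwise_variations: pd.Series  # index "V2/3", "V3/4", ...
    stability_order: list[str]  # most stable first


def _genorm_m(log_q: pd.DataFrame) -> pd.Series:
    """M_j = mean over k != j of sd(log2 q_j - log2 q_k) across samples."""
    candidates = list(log_q.index)
    m = {}
    for j in candidates:
        sds = [
            float(np.std(log_q.loc[j] - log_q.loc[k], ddof=1))
            for k in candidates
            if k != j
        ]
        m[j] = float(np.mean(sds))
    return pd.Series(m)


def genorm(values: pd.DataFrame) -> GenormResult:
    """geNorm on strictly positive relative quantities (candidates x samples)."""
    if values.shape[0] < 2:
        raise DataValidationError("geNorm needs at least 2 candidates")
    if values.shape[1] < 2:
        raise DataValidationError("geNorm needs at least 2 samples")
    if (values.values <= 0).any():
        raise DataValidationError("geNorm requires strictly positive quantities")
    log_q = np.log2(values)

    m_initial = _genorm_m(log_q)
    exclusion: list[str] = []
    remaining = log_q.copy()
    while remaining.shape[0] > 2:
        m = _genorm_m(remaining)
        worst = m.sort_values(ascending=False).index[0]
        exclusion.append(worst)
        remaining = remaining.drop(index=worst)
    final_pair = list(remaining.index)
    exclusion.extend(final_pair)

    # final pair shares rank 1; earlier exclusions get 3, 4, ... (rank 2 skipped)
    ranks = pd.Series(index=values.index, dtype=int)
    ranks[final_pair] = 1
    for i, tid in enumerate(reversed(exclusion[:-2])):
        ranks[tid] = 3 + i
    stability_order = final_pair + list(reversed(exclusion[:-2]))

    # V(n/n+1): sd across samples of log2(NF_n / NF_{n+1}), NF = geometric mean
    variations = {}
    for n in range(2, values.shape[0]):
        nf_n = log_q.loc[stability_order[:n]].mean(axis=0)
        nf_n1 = log_q.loc[stability_order[: n + 1]].mean(axis=0)
        variations[f"V{n}/{n + 1}"] = float(np.std(nf_n - nf_n1, ddof=1))

    return GenormResult(
        m_values=m_initial,
        exclusion_order=exclusion,
        ranks=ranks,
        pairwise_variations=pd.Series(variations),
        stability_order=stability_order,
    )


# ---------------------------------------------------------------------------
# NormFinder
# ---------------------------------------------------------------------------

def normfinder(values: pd.DataFrame, groups: pd.Series | None = None) -> pd.Series:
    """NormFinder stability values on log-scale quantities (candidates x samples).

    Grouped model: after removing per-sample level (subtracting each sample's
    mean over candidates), estimate for every candidate i and group g the
    intra-group variance v_ig and the inter-group bias d_ig (group mean
    centered over groups). The candidate's inter-group variance gamma_i^2 is
    a moment estimate (variance of d_ig minus the mean sampling variance of
    the group means, clipped at 0); the bias is shrunk toward zero by
    gamma^2/(gamma^2 + v_ig/n_g). SV_i is the mean over groups of
    |shrunk bias| + sqrt(v_ig/n_g), so intra-group variability contributes
    even when no group bias is detectable. With a single group (or none
    given) the fallback is the ungrouped standard deviation of the
    level-removed values.
    """
    if values.shape[0] < 3:
        raise DataValidationError("NormFinder needs at least 3 candidates")
    y = values.astype(float)
    u = y - y.mean(axis=0)  # remove per-sample level

    if groups is not None:
        groups = pd.Series(groups).reindex(y.columns)
        group_ids = [g for g in pd.unique(groups) if pd.notna(g)]
        sizes = {g: int((groups == g).sum()) for g in group_ids}
        if len(group_ids) < 2 or any(sizes[g] < 2 for g in group_ids):
            import warnings

            warnings.warn(
                "NormFinder needs >=2 groups with >=2 samples; "
                "falling back to ungrouped variability"
            )
            groups = None

    if groups is None:
        return u.std(axis=1, ddof=1).rename("SV")

    g_ids = [g for g in pd.unique(groups) if pd.notna(g)]
    n_g = {g: int((groups == g).sum()) for g in g_ids}
    a = pd.DataFrame(
        {g: u.loc[:, groups[groups == g].index].mean(axis=1) for g in g_ids}
    )
    v = pd.DataFrame(
        {g: u.loc[:, groups[groups == g].index].var(axis=1, ddof=1) for g in g_ids}
    )
    d = a.sub(a.mean(axis=1), axis=0)  # inter-group bias, centered per candidate
    G = len(g_ids)
    sampling = v.div(pd.Series(n_g)).mean(axis=1)  # mean var of the group means
    gamma2 = (d.pow(2).sum(axis=1) / (G - 1) - sampling).clip(lower=0.0)

    sv = pd.Series(0.0, index=y.index)
    for g in g_ids:
        se2 = v[g] / n_g[g]
        shrink = (gamma2 / (gamma2 + se2)).fillna(0.0)
        d_hat = d[g] * shrink  # empirical-Bayes shrinkage of the group bias
        sv += (d_hat.abs() + np.sqrt(se2)) / G
    return sv.rename("SV")


# ---------------------------------------------------------------------------
# BestKeeper
# ---------------------------------------------------------------------------

@dataclass
class BestkeeperResult:
    r: pd.Series  # Pearson correlation with the index (NaN where undefined)
    sd: pd.Series  # descriptive per-candidate sd of Cq
    index: pd.Series  # per-sample BestKeeper index (mean Cq over candidates)
    undefined: pd.Series  # constant candidates flagged, ranked last


def bestkeeper(values: pd.DataFrame) -> BestkeeperResult:
    """BestKeeper on Cq values (candidates x samples)."""
    if values.shape[0] < 2:
        raise DataValidationError("BestKeeper needs at least 2 candidates")
    y = values.astype(float)
    index = y.mean(axis=0)
    r = {}
    undefined = {}
    for tid in y.index:
        row = y.loc[tid]
        if np.std(row.values, ddof=0) == 0 or np.std(index.values, ddof=0) == 0:
            r[tid] = np.nan
            undefined[tid] = True
        else:
            r[tid] = float(stats.pearsonr(row.values, index.values)[0])
            undefined[tid] = False
    return BestkeeperResult(
        r=pd.Series(r),
        sd=y.std(axis=1, ddof=1),
        index=index,
        undefined=pd.Series(undefined),
    )


# ---------------------------------------------------------------------------
# rank integration
# ---------------------------------------------------------------------------

@dataclass
class StabilityRanking:
    table: pd.DataFrame
    # index candidate; columns M, SV, r, rank_genorm, rank_normfinder,
    # rank_bestkeeper, GM; ordered by ascending GM
    pairwise_variations: pd.Series | None = field(default=None)

    @property
    def ordering(self) -> list[str]:
        return list(self.table.index)


def competition_rank(scores: pd.Series, ascending: bool = True) -> pd.Series:
    """Competition ("min") ranks: ties share the smaller rank, next skipped.

    NaN scores rank strictly last (shared rank below all defined scores).
    """
    s = scores if ascending else -scores
    ranks = s.rank(method="min", ascending=True, na_option="bottom")
    return ranks.astype(int)


def integrate_ranks(
    m_values: pd.Series,
    sv_values: pd.Series,
    r_values: pd.Series,
    genorm_ranks: pd.Series | None = None,
    pairwise_variations: pd.Series | None = None,
) -> StabilityRanking:
    """Geometric-mean integration of the three per-method rankings.

    geNorm ranks ascend in M unless the stepwise exclusion ranks (with the
    final pair tied at 1) are supplied; NormFinder ranks ascend in SV;
    BestKeeper ranks descend in r. GM is reported to 2 decimals and orders
    the final table.
    """
    candidates = list(m_values.index)
    for other in (sv_values, r_values):
        if set(other.index) != set(candidates):
            raise DataValidationError("score lists cover different candidates")
    rank_g = (
        genorm_ranks.reindex(candidates)
        if genorm_ranks is not None
        else competition_rank(m_values, ascending=True)
    )
    rank_n = competition_rank(sv_values.reindex(candidates), ascending=True)
    rank_b = competition_rank(r_values.reindex(candidates), ascending=False)
    gm = (rank_g * rank_n * rank_b) ** (1.0 / 3.0)
    table = pd.DataFrame(
        {
            "M": m_values,
            "SV": sv_values.reindex(candidates),
            "r": r_values.reindex(candidates),
            "rank_genorm": rank_g.astype(int),
            "rank_normfinder": rank_n.astype(int),
            "rank_bestkeeper": rank_b.astype(int),
            "GM": np.round(gm, 2),
        },
        index=candidates,
    ).sort_values("GM", kind="mergesort")
    return StabilityRanking(table=table, pairwise_variations=pairwise_variations)


def rank_stability(
    cq: pd.DataFrame, groups: pd.Series | None = None, efficiency: float = 2.0
) -> StabilityRanking:
    """Full stability ranking from a candidate x sample mean-Cq matrix.

    Supplies each method its native scale: relative quantities
    efficiency**(Cq_min - Cq) for geNorm, their log2 for NormFinder, raw Cq
    for BestKeeper.
    """
    if cq.isna().any().any():
        raise DataValidationError("stability ranking needs complete Cq data")
    log2_q = (cq.min(axis=1).values[:, None] - cq.values) * np.log2(efficiency)
    rel_q = pd.DataFrame(2.0**log2_q, index=cq.index, columns=cq.columns)
    g = genorm(rel_q)
    sv = normfinder(pd.DataFrame(log2_q, index=cq.index, columns=cq.columns), groups)
    bk = bestkeeper(cq)
    return integrate_ranks(
        g.m_values,
        sv,
        bk.r,
        genorm_ranks=g.ranks,
        pairwise_variations=g.pairwise_variations,
    )
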