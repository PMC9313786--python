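"""Pairwise negative-binomial differential expression between stages.

The testing chain mirrors the classic count-based workflow: filter weakly
expressed transcripts, compute TMM effective library sizes, estimate a
common NB dispersion by conditional maximum likelihood on library-equalized
pseudo-counts, apply a two-sided exact test per transcript conditioning on
the pairwise total, and control FDR by Benjamini-Hochberg. Direction calls
use inclusive thresholds: FDR <= alpha and |log2FC| >= lfc.

The NB parameterization throughout is variance = mu + phi * mu^2. A sum of
n i.i.d. NB(mu, phi) replicates is NB(n*mu, phi/n), which is how group sums
inherit their dispersion. Tagwise empirical-Bayes dispersion shrinkage is
deliberately not implemented; a single common dispersion is used.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import optimize, special

from .data_model import CountMatrix, DataValidationError, SampleSheet, validate_stage
from .normalize import tmm_factors, to_cpm

DEFAULT_ALPHA = 0.05
DEFAULT_LFC = 1.5


@dataclass
class DispersionEstimate:
    common_phi: float
    method: str = "qCML-common"

    def __post_init__(self) -> None:
        if self.common_phi < 0:
            raise DataValidationError("dispersion must be non-negative")


@dataclass
class ContrastResult:
    """Exact-test results for stage_b vs stage_a (log2FC is B relative to A)."""

    stage_a: str
    stage_b: str
    table: pd.DataFrame  # index transcript_id; columns log2FC, p_value, FDR, direction
    dispersion: DispersionEstimate

    @property
    def significant(self) -> pd.Index:
        return self.table.index[self.table["direction"] != "ns"]

    def significant_up(self) -> pd.Index:
        return self.table.index[self.table["direction"] == "up"]

    def significant_down(self) -> pd.Index:
        return self.table.index[self.table["direction"] == "down"]


# ---------------------------------------------------------------------------
# expression filter
# ---------------------------------------------------------------------------

def filter_expressed(
    counts: CountMatrix, min_samples: int = 3, min_total_cpm: float = 3.0
) -> CountMatrix:
    """Keep transcripts with >=1 count in at least ``min_samples`` samples AND
    a summed CPM across samples of at least ``min_total_cpm`` (inclusive)."""
    cpm = to_cpm(counts).values
    n_nonzero = (counts.counts.values > 0).sum(axis=1)
    total_cpm = cpm.sum(axis=1).values
    keep = (n_nonzero >= min_samples) & (total_cpm >= min_total_cpm)
    if not keep.any():
        raise DataValidationError(
            "expression filter removed every transcript; review min_samples/min_total_cpm"
        )
    return counts.subset_transcripts(counts.counts.index[keep])


# ---------------------------------------------------------------------------
# common dispersion (conditional maximum likelihood on equalized counts)
# ---------------------------------------------------------------------------

def _equalize_libraries(counts: np.ndarray, lib_sizes: np.ndarray) -> np.ndarray:
    """Scale each sample's counts to the geometric-mean library size.

    A linear stand-in for quantile adjustment: exact when libraries are
    already equal, and adequate for the moderate depth ratios simulated here.
    """
    target = np.exp(np.mean(np.log(lib_sizes)))
    return counts * (target / lib_sizes)


def _conditional_loglik(phi: float, pseudo: np.ndarray, group_sizes: list[np.ndarray]) -> float:
    """NB conditional log-likelihood given group totals, summed over transcripts.

    For a group of n replicates with counts y_i and total z, conditioning on z
    removes the mean: l(phi) = sum_i lgamma(y_i + r) - n*lgamma(r)
    + lgamma(n*r) - lgamma(z + n*r), with r = 1/phi.
    """
    r = 1.0 / phi
    total = 0.0
    for cols in group_sizes:
        y = pseudo[:, cols]
        n = y.shape[1]
        z = y.sum(axis=1)
        total += float(
            np.sum(special.gammaln(y + r))
            - y.shape[0] * n * special.gammaln(r)
            + np.sum(special.gammaln(n * r) - special.gammaln(z + n * r))
        )
    return total


def estimate_common_dispersion(
    counts: CountMatrix,
    groups: pd.Series | None = None,
    bounds: tuple[float, float] = (1e-6, 10.0),
) -> DispersionEstimate:
    """Single dispersion maximizing the conditional NB likelihood across groups."""
    if groups is None:
        groups = counts.samples.stages
    groups = pd.Series(groups).reindex(counts.counts.columns)
    group_cols: list[np.ndarray] = []
    for _, members in groups.groupby(groups):
        cols = np.array([counts.counts.columns.get_loc(s) for s in members.index])
        if len(cols) < 2:
            raise DataValidationError(
                "dispersion estimation needs >=2 replicates per group"
            )
        group_cols.append(cols)
    if len(group_cols) < 2 and len(group_cols[0]) < 2:
        raise DataValidationError("need >=2 groups with >=2 replicates each")

    pseudo = _equalize_libraries(
        counts.counts.values.astype(float), counts.library_sizes.values.astype(float)
    )
    # restrict to transcripts with some signal; all-zero rows carry no information
    keep = pseudo.sum(axis=1) > 0
    pseudo = pseudo[keep]

    res = optimize.minimize_scalar(
        lambda lp: -_conditional_loglik(np.exp(lp), pseudo, group_cols),
        bounds=(np.log(bounds[0]), np.log(bounds[1])),
        method="bounded",
        options={"xatol": 1e-8},
    )
    phi = float(np.exp(res.x))
    if phi <= bounds[0] * 1.01 or phi >= bounds[1] * 0.99:
        warnings.warn(f"common dispersion estimate at search boundary: {phi:.3g}")
    return DispersionEstimate(common_phi=phi)


# ---------------------------------------------------------------------------
# exact test
# ---------------------------------------------------------------------------

def _nb_logpmf(x: np.ndarray, mu: float, phi: float) -> np.ndarray:
    if mu == 0:
        out = np.full_like(x, -np.inf, dtype=float)
        out[x == 0] = 0.0
        return out
    if phi <= 0:
        return x * np.log(mu) - mu - special.gammaln(x + 1)
    r = 1.0 / phi
    p = r / (r + mu)
    return (
        special.gammaln(x + r)
        - special.gammaln(r)
        - special.gammaln(x + 1)
        + r * np.log(p)
        + x * np.log1p(-p)
    )


def nb_exact_test(
    counts_a, counts_b, lib_a: float = 1.0, lib_b: float = 1.0, phi: float = 0.0
) -> float:
    """Two-sided exact NB test for a difference between two groups of counts.

    Group counts are summed (a sum of n i.i.d. NB replicates is NB with
    dispersion phi/n); conditioning on the grand total, the p-value sums the
    probabilities of all splits no more likely than the observed one. With
    phi = 0 this reduces to the exact conditional binomial split test.
    """
    a = np.atleast_1d(np.asarray(counts_a, dtype=float))
    b = np.atleast_1d(np.asarray(counts_b, dtype=float))
    if (a < 0).any() or (b < 0).any():
        raise DataValidationError("counts must be non-negative")
    if lib_a <= 0 or lib_b <= 0:
        raise DataValidationError("library sizes must be positive")
    sum_a, sum_b = float(a.sum()), float(b.sum())
    total = int(round(sum_a + sum_b))
    if total == 0:
        return 1.0
    phi_a = phi / len(a)
    phi_b = phi / len(b)
    frac_a = lib_a / (lib_a + lib_b)
    mu_a = total * frac_a
    mu_b = total - mu_a
    x = np.arange(total + 1, dtype=float)
    logp = _nb_logpmf(x, mu_a, phi_a) + _nb_logpmf(total - x, mu_b, phi_b)
    logp -= special.logsumexp(logp)
    obs = int(round(sum_a))
    # tolerance so ties (e.g. the symmetric split) are included on both sides
    mask = logp <= logp[obs] + 1e-10
    return float(min(1.0, np.exp(special.logsumexp(logp[mask]))))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise DataValidationError("p-values must be a 1-D sequence")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise DataValidationError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


# ---------------------------------------------------------------------------
# full contrast
# ---------------------------------------------------------------------------

def run_contrast(
    counts: CountMatrix,
    stage_a: str,
    stage_b: str,
    alpha: float = DEFAULT_ALPHA,
    lfc: float = DEFAULT_LFC,
    dispersion: DispersionEstimate | None = None,
    prior_count: float = 0.5,
) -> ContrastResult:
    """TMM-scaled exact test of stage_b vs stage_a with BH adjustment.

    log2FC is computed from effective-library CPM group means with a
    ``prior_count`` offset to avoid infinities.
    """
    validate_stage(stage_a)
    validate_stage(stage_b)
    sheet = counts.samples
    samples_a = sheet.samples_of_stage(stage_a)
    samples_b = sheet.samples_of_stage(stage_b)
    if not samples_a or not samples_b:
        raise DataValidationError(f"stage(s) absent from sheet: {stage_a}/{stage_b}")
    pair = counts.subset_samples(samples_a + samples_b)

    factors = tmm_factors(pair)
    eff_libs = pair.library_sizes.astype(float) * factors
    if dispersion is None:
        dispersion = estimate_common_dispersion(pair, pair.samples.stages)
    phi = dispersion.common_phi

    # equalize to the geometric-mean effective library so group sums are
    # comparable; rounded pseudo-counts feed the exact test
    target = float(np.exp(np.mean(np.log(eff_libs.values))))
    pseudo = pair.counts.values.astype(float) * (target / eff_libs.values)
    idx_a = [pair.counts.columns.get_loc(s) for s in samples_a]
    idx_b = [pair.counts.columns.get_loc(s) for s in samples_b]
    pseudo_a = np.round(pseudo[:, idx_a])
    pseudo_b = np.round(pseudo[:, idx_b])

    p_values = np.array(
        [
            nb_exact_test(pseudo_a[i], pseudo_b[i], 1.0, 1.0, phi)
            for i in range(pseudo.shape[0])
        ]
    )
    fdr = bh_adjust(p_values)

    cpm = to_cpm(pair, factors).values
    mean_a = cpm[samples_a].mean(axis=1) + prior_count / (target / 1e6)
    mean_b = cpm[samples_b].mean(axis=1) + prior_count / (target / 1e6)
    log2fc = np.log2(mean_b.values / mean_a.values)

    direction = np.where(
        (fdr <= alpha) & (np.abs(log2fc) >= lfc),
        np.where(log2fc > 0, "up", "down"),
        "ns",
    )
    table = pd.DataFrame(
        {
            "log2FC": log2fc,
            "p_value": p_values,
            "FDR": fdr,
            "direction": direction,
        },
        index=pair.counts.index,
    )
    return ContrastResult(stage_a=stage_a, stage_b=stage_b, table=table, dispersion=dispersion)


def all_pairwise_contrasts(
    counts: CountMatrix,
    alpha: float = DEFAULT_ALPHA,
    lfc: float = DEFAULT_LFC,
    dispersion: DispersionEstimate | None = None,
) -> dict[tuple[str, str], ContrastResult]:
    """All-versus-all stage contrasts on the stages present in the sheet."""
    stages = counts.samples.stages_present()
    if dispersion is None:
        dispersion = estimate_common_dispersion(counts)
    return {
        (a, b): run_contrast(counts, a, b, alpha=alpha, lfc=lfc, dispersion=dispersion)
        for a, b in combinations(stages, 2)
    }


def stage_overlap_sets(results: dict[str, ContrastResult]) -> dict[str, set[str]]:
    """Venn regions of the significant sets of three contrasts vs a common
    reference, keyed like "SWE", "SWE&ATT", "SWE&ATT&PEN" plus "<stage>_up"
    and "<stage>_down" count sets per contrast."""
    if len(results) != 3:
        raise DataValidationError("need exactly three contrasts for the Venn regions")
    universes = [frozenset(r.table.index) for r in results.values()]
    if len(set(universes)) != 1:
        raise DataValidationError("contrasts do not share a transcript universe")
    sig = {name: set(r.significant) for name, r in results.items()}
    names = list(sig)
    regions: dict[str, set[str]] = {}
    for k in (1, 2, 3):
        for combo in combinations(names, k):
            inside = set.intersection(*(sig[n] for n in combo))
            outside = set.union(set(), *(sig[n] for n in names if n not in combo))
            regions["&".join(combo)] = inside - outside
    for name, r in results.items():
        regions[f"{name}_up"] = set(r.significant_up())
        regions[f"{name}_down"] = set(r.significant_down())
    return regions
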