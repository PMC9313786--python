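"""Hypergeometric over-representation of functional bins with BH control.

Bin codes are dot-separated hierarchies (MapMan-style); by default a
transcript annotated to "15.5.30" also counts toward the ancestor bins
"15.5" and "15", so top-level category summaries aggregate their leaves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

from .data_model import AnnotationTable, DataValidationError
from .diffexp import bh_adjust


def _log_comb(n, k):
    return special.gammaln(n + 1) - special.gammaln(k + 1) - special.gammaln(n - k + 1)


def hypergeom_upper(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N population, K marked,
    n drawn), computed exactly from log-factorial sums."""
    if not (0 <= k <= min(n, K) and 0 <= n <= N and 0 <= K <= N):
        raise DataValidationError(
            f"inconsistent hypergeometric counts k={k}, n={n}, K={K}, N={N}"
        )
    if k == 0:
        return 1.0
    xs = np.arange(k, min(n, K) + 1)
    log_terms = _log_comb(K, xs) + _log_comb(N - K, n - xs) - _log_comb(N, n)
    return float(min(1.0, np.exp(special.logsumexp(log_terms))))


def expand_bincode(bincode: str) -> list[str]:
    """All hierarchy levels of a dot-separated bin code, leaf included."""
    parts = str(bincode).split(".")
    return [".".join(parts[: i + 1]) for i in range(len(parts))]


@dataclass
class EnrichmentResult:
    table: pd.DataFrame  # index bincode; columns k, n, K, N, p_value, FDR, enriched

    def enriched_bins(self) -> list[str]:
        return self.table.index[self.table["enriched"]].tolist()


def enrich_bins(
    selected: set[str],
    universe: set[str],
    annot: AnnotationTable,
    alpha: float = 0.05,
    expand_hierarchy: bool = True,
) -> EnrichmentResult:
    """One upper-tail hypergeometric test per bin with >=1 universe member,
    BH-adjusted across tested bins; enriched iff FDR <= alpha."""
    selected = set(selected)
    universe = set(universe)
    if not selected <= universe:
        extra = sorted(selected - universe)[:5]
        raise DataValidationError(f"selected set not within universe, e.g. {extra}")
    membership: dict[str, set[str]] = {}
    for tid, bincode in zip(annot.table["transcript_id"], annot.table["bincode"]):
        if tid not in universe:
            continue
        bins = expand_bincode(bincode) if expand_hierarchy else [str(bincode)]
        for b in bins:
            membership.setdefault(b, set()).add(tid)
    if not membership:
        raise DataValidationError("no annotated transcripts in the universe")
    N, n = len(universe), len(selected)
    rows = []
    for bincode in sorted(membership):
        members = membership[bincode]
        K = len(members)
        k = len(members & selected)
        rows.append(
            {
                "bincode": bincode,
                "k": k,
                "n": n,
                "K": K,
                "N": N,
                "p_value": hypergeom_upper(k, n, K, N),
            }
        )
    table = pd.DataFrame(rows).set_index("bincode")
    table["FDR"] = bh_adjust(table["p_value"].values)
    table["enriched"] = table["FDR"] <= alpha
    return EnrichmentResult(table=table)
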