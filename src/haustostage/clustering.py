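"""Two-dimensional hierarchical clustering of z-scored expression profiles.

Complete linkage on Euclidean distances, cut to k flat clusters (the
analysis default is k = 12 overarching expression clusters), with per-cluster
per-stage mean z-score profiles. Dendrograms can be serialized to newick.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .data_model import DataValidationError, ExpressionMatrix, SampleSheet

DEFAULT_K = 12


@dataclass
class Dendrogram:
    """Linkage tree over named items (a thin wrapper around a scipy linkage)."""

    linkage: np.ndarray
    labels: list[str]
    axis: str

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def walk(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return walk(tree, tree.dist) + ";"


@dataclass
class ClusterAssignment:
    assignment: pd.Series  # item -> cluster id in 1..k
    dendrogram: Dendrogram
    k: int


def hierarchical_cluster(matrix: ExpressionMatrix, axis: str = "rows") -> Dendrogram:
    """Complete-linkage agglomeration on Euclidean distances along one axis."""
    if axis not in ("rows", "columns"):
        raise DataValidationError("axis must be 'rows' or 'columns'")
    data = matrix.values.values if axis == "rows" else matrix.values.values.T
    labels = list(matrix.values.index if axis == "rows" else matrix.values.columns)
    if data.shape[0] < 2:
        raise DataValidationError("need at least 2 items to cluster")
    if not np.isfinite(data).all():
        raise DataValidationError("clustering input contains non-finite values")
    linkage = hierarchy.linkage(pdist(data, metric="euclidean"), method="complete")
    return Dendrogram(linkage=linkage, labels=labels, axis=axis)


def cut_to_k(dendrogram: Dendrogram, k: int) -> ClusterAssignment:
    """Cut the tree into exactly k flat clusters.

    Cluster ids are relabeled 1..k by decreasing size, ties broken by the
    first member's position in the input order.
    """
    n = len(dendrogram.labels)
    if not 1 <= k <= n:
        raise DataValidationError(f"k={k} out of range 1..{n}")
    flat = hierarchy.fcluster(dendrogram.linkage, t=k, criterion="maxclust")
    if len(np.unique(flat)) != k:
        # exact-k cut defeated by tied merge heights; fall back to cutting at
        # a height between merges
        heights = np.sort(dendrogram.linkage[:, 2])
        cut = heights[n - k - 1] if k < n else -1.0
        flat = hierarchy.fcluster(dendrogram.linkage, t=cut, criterion="distance")
    raw = pd.Series(flat, index=dendrogram.labels)
    sizes = raw.value_counts()
    first_pos = {cid: int(np.argmax(raw.values == cid)) for cid in sizes.index}
    ordered = sorted(sizes.index, key=lambda cid: (-sizes[cid], first_pos[cid]))
    relabel = {old: new for new, old in enumerate(ordered, start=1)}
    return ClusterAssignment(
        assignment=raw.map(relabel), dendrogram=dendrogram, k=len(ordered)
    )


def cluster_profiles(
    assignment: ClusterAssignment, matrix: ExpressionMatrix, sheet: SampleSheet
) -> pd.DataFrame:
    """Per-cluster, per-stage mean z-score over member transcripts and replicates."""
    common = assignment.assignment.index.intersection(matrix.values.index)
    if len(common) == 0:
        raise DataValidationError("assignment and matrix share no transcripts")
    stage_of = sheet.stages
    profiles = {}
    for cid, members in assignment.assignment.loc[common].groupby(assignment.assignment.loc[common]):
        block = matrix.values.loc[members.index]
        if block.empty:
            warnings.warn(f"cluster {cid} is empty; excluded from profiles")
            continue
        profiles[cid] = block.T.groupby(stage_of).mean().mean(axis=1)
    out = pd.DataFrame(profiles).T
    out.index.name = "cluster"
    return out[[s for s in sheet.stages_present() if s in out.columns]]
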