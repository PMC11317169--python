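"""Pearson-correlation distances and hierarchical clustering of footprints.

Footprints (median RN vectors over the panel) from different target
conditions are compared by the correlation distance d = 1 - Pearson r,
then clustered agglomeratively; branch lengths of the resulting
dendrogram reflect footprint dissimilarity, so conditions probing
structurally similar targets cluster together.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy import stats
from skbio.tree import TreeNode

LINKAGE_METHODS = ("average", "single", "complete")


def pearson_distance(
    fp_matrix: pd.DataFrame, centered: bool = True
) -> pd.DataFrame:
    """Pairwise 1 - Pearson r between footprint columns.

    ``fp_matrix`` is members x conditions (the median footprint matrix).
    ``centered=False`` uses the uncentered correlation (cosine of the raw
    vectors), a variant some heat-map viewers offer.
    """
    if fp_matrix.shape[1] < 2:
        raise ValueError("need at least 2 conditions")
    if fp_matrix.shape[0] < 3:
        raise ValueError("need at least 3 panel members")
    X = fp_matrix.to_numpy(dtype=float)
    if centered:
        sd = X.std(axis=0)
        for j, s in enumerate(sd):
            if s == 0:
                raise ValueError(
                    f"zero-variance footprint for condition {fp_matrix.columns[j]!r}"
                )
        corr = np.corrcoef(X.T)
    else:
        norms = np.linalg.norm(X, axis=0)
        for j, s in enumerate(norms):
            if s == 0:
                raise ValueError(
                    f"all-zero footprint for condition {fp_matrix.columns[j]!r}"
                )
        corr = (X.T @ X) / np.outer(norms, norms)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, 2.0)
    labels = list(fp_matrix.columns)
    return pd.DataFrame(dist, index=labels, columns=labels)


@dataclass
class DistanceTree:
    """A distance matrix with its agglomerative tree.

    ``linkage_matrix`` follows the scipy convention; ``newick`` is the
    rooted serialization with branch lengths derived from merge heights.
    """

    labels: list[str]
    dist: pd.DataFrame
    linkage_matrix: np.ndarray
    method: str
    newick: str

    def cut(self, k: int) -> dict[str, int]:
        """Flat clustering into ``k`` groups (labels -> 1-based cluster id)."""
        assignments = hierarchy.fcluster(self.linkage_matrix, k, criterion="maxclust")
        return dict(zip(self.labels, (int(a) for a in assignments)))

    def write_newick(self, path: str | Path) -> None:
        Path(path).write_text(self.newick + "\n")


def hierarchical_cluster(
    dist: pd.DataFrame, method: str = "average"
) -> DistanceTree:
    """Agglomerative clustering of a condition-distance matrix.

    Labels are sorted lexicographically before linkage so that ties in
    merge heights resolve toward the lexicographically smallest pair,
    making the tree deterministic.  Average linkage is the default of the
    Cluster-3.0 / TreeView family of tools.
    """
    if method not in LINKAGE_METHODS:
        raise ValueError(f"linkage must be one of {LINKAGE_METHODS}")
    labels = sorted(str(c) for c in dist.columns)
    if len(labels) == 1:
        import warnings

        warnings.warn("single condition: trivial one-leaf tree")
        return DistanceTree(
            labels=labels,
            dist=dist,
            linkage_matrix=np.empty((0, 4)),
            method=method,
            newick=f"{labels[0]}:0;",
        )
    d = dist.loc[labels, labels]
    condensed = squareform(d.to_numpy(dtype=float), checks=False)
    Z = hierarchy.linkage(condensed, method=method)
    tree = TreeNode.from_linkage_matrix(Z, labels)
    newick = str(tree).strip()
    return DistanceTree(
        labels=labels, dist=d, linkage_matrix=Z, method=method, newick=newick
    )


def replicate_r2(rep_a: Sequence[float], rep_b: Sequence[float]) -> float:
    """Squared Pearson correlation between two replicate RN vectors."""
    a = np.asarray(rep_a, dtype=float)
    b = np.asarray(rep_b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("replicate vectors must share a length >= 3")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("replicate vector has zero variance")
    r, _ = stats.pearsonr(a, b)
    return float(r**2)


def write_cdt_gtr(
    fp_matrix: pd.DataFrame, tree: DistanceTree, prefix: str | Path
) -> None:
    """Export a Cluster-3.0-style .cdt/.gtr pair for TreeView-family GUIs.

    Rows of the .cdt are the clustered conditions (one footprint per
    row); the .gtr records the merge order with similarities 1 - height.
    """
    prefix = Path(prefix)
    labels = tree.labels
    n = len(labels)
    Z = tree.linkage_matrix
    with open(prefix.with_suffix(".gtr"), "w") as fh:
        for i, (a, b, height, _) in enumerate(Z):
            ida = f"GENE{int(a)}X" if a < n else f"NODE{int(a) - n + 1}X"
            idb = f"GENE{int(b)}X" if b < n else f"NODE{int(b) - n + 1}X"
            fh.write(f"NODE{i + 1}X\t{ida}\t{idb}\t{1.0 - height:.6f}\n")
    leaf_order = hierarchy.leaves_list(Z) if len(Z) else [0]
    members = list(fp_matrix.index)
    with open(prefix.with_suffix(".cdt"), "w") as fh:
        fh.write("GID\tUNIQID\tNAME\tGWEIGHT\t" + "\t".join(members) + "\n")
        fh.write("EWEIGHT\t\t\t\t" + "\t".join(["1"] * len(members)) + "\n")
        for idx in leaf_order:
            label = labels[idx]
            values = fp_matrix[label].reindex(members)
            fh.write(
                f"GENE{idx}X\t{label}\t{label}\t1\t"
                + "\t".join(f"{v:.6f}" for v in values)
                + "\n"
            )
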