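"""Hamming-distance computation and average-linkage (UPGMA) clustering of
binary strain profiles, with Newick / merge-table export.

Profiles are equal-length 0/1 vectors per strain — growth across
environments, SCFA production flags, or single-lethality indicators. The
distance between two strains is the *proportion* of positions at which their
profiles differ (Hamming proportion), which keeps profiles of different
semantic length comparable. Trees are phenetic dendrograms, not phylogenies.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from skbio.tree import TreeNode

from .phenotyping import PhenotypeMatrix


@dataclass
class BinaryProfileSet:
    """Equal-length binary vectors, one per strain."""

    row_labels: list[str]
    profiles: np.ndarray  # shape (n_strains, n_features), values in {0, 1}

    def __post_init__(self) -> None:
        self.profiles = np.asarray(self.profiles)
        if self.profiles.ndim != 2:
            raise ValueError("profiles must be a 2-D array (strains x features)")
        if self.profiles.shape[0] != len(self.row_labels):
            raise ValueError("profile rows must match row labels")
        if not np.isin(self.profiles, (0, 1)).all():
            raise ValueError("profiles must be binary (0/1)")

    @classmethod
    def from_phenotype_matrix(cls, matrix: PhenotypeMatrix) -> "BinaryProfileSet":
        return cls(
            row_labels=list(matrix.row_labels),
            profiles=np.array(matrix.values, dtype=int),
        )


@dataclass
class DendrogramTree:
    """UPGMA merge tree: a scipy linkage matrix plus leaf labels.

    Each merge row is (child, child, height, size); heights are average
    Hamming distances and are non-decreasing from leaves to root.
    """

    linkage_matrix: np.ndarray
    leaf_labels: list[str]

    @property
    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def cut(self, k: int) -> dict[str, int]:
        """Flat clusters from cutting the tree into k groups."""
        assignment = fcluster(self.linkage_matrix, t=k, criterion="maxclust")
        return dict(zip(self.leaf_labels, (int(a) for a in assignment)))

    def to_newick(self) -> str:
        tree = TreeNode.from_linkage_matrix(self.linkage_matrix, self.leaf_labels)
        buf = io.StringIO()
        tree.write(buf, format="newick")
        return buf.getvalue().strip()


def hamming_distance_matrix(profiles: BinaryProfileSet) -> np.ndarray:
    """Symmetric matrix of pairwise Hamming proportions (mismatch fraction)."""
    if len(profiles.row_labels) < 2:
        raise ValueError("need at least two profiles")
    return squareform(pdist(profiles.profiles, metric="hamming"))


def average_linkage_tree(
    distances: np.ndarray, labels: list[str]
) -> DendrogramTree:
    """UPGMA tree from a symmetric distance matrix."""
    distances = np.asarray(distances, dtype=float)
    if distances.ndim != 2 or distances.shape[0] != distances.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(distances, distances.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if distances.shape[0] != len(labels):
        raise ValueError("label count must match matrix size")
    condensed = squareform(distances, checks=False)
    Z = linkage(condensed, method="average")
    return DendrogramTree(linkage_matrix=Z, leaf_labels=list(labels))


def cluster_profiles(profiles: BinaryProfileSet) -> DendrogramTree:
    """Hamming distances + UPGMA in one step."""
    return average_linkage_tree(
        hamming_distance_matrix(profiles), profiles.row_labels
    )


# ---------------------------------------------------------------------------
# Export / import
# ---------------------------------------------------------------------------


def export_tree(tree: DendrogramTree, path: str, format: str = "newick") -> None:
    """Write the tree as Newick (branch lengths = parent height - child
    height) or as a merge table (child, child, height, size)."""
    if format == "newick":
        with open(path, "w") as fh:
            fh.write(tree.to_newick() + "\n")
    elif format == "merge-table":
        import pandas as pd

        df = pd.DataFrame(
            tree.linkage_matrix,
            columns=["child_a", "child_b", "height", "size"],
        )
        df.insert(0, "node", np.arange(len(tree.leaf_labels), len(tree.leaf_labels) + len(df)))
        header = "# leaves: " + "\t".join(tree.leaf_labels) + "\n"
        with open(path, "w") as fh:
            fh.write(header)
            df.to_csv(fh, sep="\t", index=False)
    else:
        raise ValueError(f"unknown tree format {format!r}")


def import_merge_table(path: str) -> DendrogramTree:
    import pandas as pd

    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# leaves:"):
            raise ValueError(f"{path}: missing '# leaves:' header")
        labels = first[len("# leaves:"):].strip().split("\t")
        df = pd.read_csv(fh, sep="\t")
    Z = df[["child_a", "child_b", "height", "size"]].to_numpy(dtype=float)
    return DendrogramTree(linkage_matrix=Z, leaf_labels=labels)


def read_newick(path_or_string: str) -> TreeNode:
    """Parse a Newick tree (a path or a literal string)."""
    import os

    if os.path.exists(path_or_string):
        return TreeNode.read(path_or_string, format="newick")
    return TreeNode.read(io.StringIO(path_or_string), format="newick")


def adjusted_rand_index(labels_a: dict[str, int], labels_b: dict[str, int]) -> float:
    """Agreement between two flat clusterings of the same strains (1 = same
    partition up to relabeling)."""
    if set(labels_a) != set(labels_b):
        raise ValueError("clusterings cover different strain sets")
    keys = sorted(labels_a)
    a = [labels_a[k] for k in keys]
    b = [labels_b[k] for k in keys]
    from sklearn.metrics import adjusted_rand_score

    return float(adjusted_rand_score(a, b))
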