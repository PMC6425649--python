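"""Hierarchical clustering of breeds by risk-allele frequencies.

Breeds are represented by their allele-B frequency vectors over the
candidate marker set and clustered by arithmetic average linkage (UPGMA)
on Euclidean distances.  Breeds with fewer than a minimum number of
genotyped individuals are excluded before clustering, and missing
frequencies are imputed by the marker (column) mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, linkage, to_tree
from scipy.spatial.distance import pdist, squareform


@dataclass
class Dendrogram:
    labels: list[str]
    linkage_matrix: np.ndarray  # scipy (n-1, 4) merge list
    cophenetic: np.ndarray  # condensed cophenetic distances
    newick: str

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def cophenetic_square(self) -> np.ndarray:
        return squareform(self.cophenetic)


def breed_frequency_matrix(
    freq_table: pd.DataFrame,
    markers: Sequence[str],
    min_individuals: int = 5,
) -> tuple[pd.DataFrame, int]:
    """Breeds x markers frequency matrix, filtered and mean-imputed.

    ``freq_table`` is the per-breed table from
    :func:`breedgwas.io.allele_frequencies` (columns group, marker_id,
    freq_B, n).  Breeds with fewer than ``min_individuals`` genotyped
    individuals (at every candidate marker) are dropped; missing
    frequencies are imputed by the column mean.  Returns the matrix and
    the number of imputed cells.
    """
    sub = freq_table[freq_table["marker_id"].isin(markers)]
    wide = sub.pivot(index="group", columns="marker_id", values="freq_B")
    counts = sub.pivot(index="group", columns="marker_id", values="n")
    missing_cols = [m for m in markers if m not in wide.columns]
    if missing_cols:
        raise ValueError(f"markers absent from frequency table: {missing_cols}")
    wide = wide[list(markers)]
    counts = counts[list(markers)]
    enough = counts.max(axis=1) >= min_individuals
    if not enough.any():
        raise ValueError(f"no breed has >= {min_individuals} genotyped individuals")
    wide = wide[enough]
    n_imputed = int(wide.isna().to_numpy().sum())
    if n_imputed:
        warnings.warn(f"imputing {n_imputed} missing frequencies by column mean",
                      stacklevel=2)
        wide = wide.fillna(wide.mean(axis=0))
    return wide, n_imputed


def _to_newick(node, labels: list[str], parent_height: float) -> str:
    if node.is_leaf():
        return f"{labels[node.id]}:{(parent_height / 2.0):.10g}"
    left = _to_newick(node.left, labels, node.dist)
    right = _to_newick(node.right, labels, node.dist)
    blen = (parent_height - node.dist) / 2.0
    return f"({left},{right}):{blen:.10g}"


def cluster_average_linkage(matrix: pd.DataFrame | np.ndarray,
                            labels: Sequence[str] | None = None) -> Dendrogram:
    """UPGMA (arithmetic average linkage) over breed frequency vectors.

    Distances are Euclidean between rows; merge heights are the average of
    all cross-pair original distances, so the cophenetic matrix is
    ultrametric.  The tree is also exported as Newick with ultrametric
    branch lengths (leaf depth = merge height / 2).
    """
    if isinstance(matrix, pd.DataFrame):
        labels = list(matrix.index)
        data = matrix.to_numpy(dtype=float)
    else:
        data = np.asarray(matrix, dtype=float)
        labels = list(labels) if labels is not None else [str(i) for i in range(len(data))]
    if data.shape[0] < 2:
        raise ValueError("need at least 2 rows to cluster")
    d = pdist(data, metric="euclidean")
    Z = linkage(d, method="average")
    coph = cophenet(Z)
    root = to_tree(Z)
    newick = "(" + _to_newick(root.left, labels, root.dist) + "," + \
        _to_newick(root.right, labels, root.dist) + ");"
    return Dendrogram(labels=labels, linkage_matrix=Z, cophenetic=coph, newick=newick)


def write_dendrogram(dend: Dendrogram, newick_path, heights_path=None) -> None:
    with open(newick_path, "w") as fh:
        fh.write(dend.newick + "\n")
    if heights_path is not None:
        pd.DataFrame(
            dend.linkage_matrix,
            columns=["cluster_a", "cluster_b", "height", "n_members"],
        ).to_csv(heights_path, sep="\t", index=False)
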