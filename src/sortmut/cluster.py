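"""Sample clustering of single-mutation patterns.

Replicates of the same (plasmid, gate) condition should show near-identical
mutation patterns; conditions that select different phenotypes should not.
This is checked by row-standardizing the mutation-fraction table (each
mutation scored relative to the other samples in its row, as in a heatmap
with a per-row color scale), hierarchically clustering the sample columns,
and scoring whether each condition's replicates form their own clade.

The agglomerative routine is written out explicitly so that tie-breaking is
contractual (closest pair; ties broken toward the lowest column indices) and
so that merge heights can be exported directly as Newick branch lengths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform


def pattern_matrix(fraction_table: pd.DataFrame) -> pd.DataFrame:
    """Row-standardize a fraction table: zero mean, unit population SD per row.

    Constant rows (including all-zero rows) carry no contrast and map to all
    zeros.
    """
    if fraction_table.shape[1] < 2:
        raise ValueError("need at least 2 samples to standardize across")
    x = fraction_table.values.astype(float)
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)  # population SD (ddof=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (x - mean) / sd
    z[np.broadcast_to(sd == 0, z.shape)] = 0.0
    return pd.DataFrame(z, index=fraction_table.index, columns=fraction_table.columns)


@dataclass
class ClusterNode:
    """A node of the sample dendrogram; leaves have height 0 and a label."""

    height: float
    label: str | None = None
    children: tuple["ClusterNode", "ClusterNode"] | None = None

    @property
    def is_leaf(self) -> bool:
        return self.children is None

    def leaves(self) -> tuple[str, ...]:
        if self.is_leaf:
            return (self.label,)
        return self.children[0].leaves() + self.children[1].leaves()


@dataclass
class Dendrogram:
    """Result of agglomerative clustering over sample columns."""

    root: ClusterNode
    labels: list[str]
    merge_heights: list[float]

    def leaf_order(self) -> list[str]:
        return list(self.root.leaves())

    def clades(self) -> list[frozenset]:
        """Leaf sets of every node (leaves included)."""
        out = []

        def walk(node: ClusterNode):
            out.append(frozenset(node.leaves()))
            if not node.is_leaf:
                walk(node.children[0])
                walk(node.children[1])

        walk(self.root)
        return out

    def to_newick(self) -> str:
        """Newick string with branch lengths = parent height - child height."""

        def render(node: ClusterNode, parent_height: float) -> str:
            length = parent_height - node.height
            if node.is_leaf:
                return f"{node.label}:{length:.10g}"
            left = render(node.children[0], node.height)
            right = render(node.children[1], node.height)
            return f"({left},{right}):{length:.10g}"

        if self.root.is_leaf:
            return f"{self.root.label}:0;"
        left = render(self.root.children[0], self.root.height)
        right = render(self.root.children[1], self.root.height)
        return f"({left},{right});"


_LINKAGES = ("complete", "single", "average")


def cluster_samples(
    matrix: pd.DataFrame,
    metric: str = "euclidean",
    linkage: str = "complete",
) -> Dendrogram:
    """Agglomerative clustering of the sample columns of *matrix*.

    Deterministic: at every step the closest active pair is merged, with
    exact ties resolved toward the pair with the lowest column indices
    (lexicographically).  Heights are the linkage distances at each merge.
    """
    if linkage not in _LINKAGES:
        raise ValueError(f"linkage must be one of {_LINKAGES}")
    labels = list(matrix.columns)
    n = len(labels)
    if n < 2:
        raise ValueError("need at least 2 samples to cluster")
    D = squareform(pdist(matrix.values.T, metric=metric))

    nodes: dict[int, ClusterNode] = {
        i: ClusterNode(height=0.0, label=labels[i]) for i in range(n)
    }
    sizes = {i: 1 for i in range(n)}
    active = list(range(n))
    dist = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = float(D[i, j])
    heights: list[float] = []
    next_id = n
    while len(active) > 1:
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                d = dist[(i, j)]
                if best is None or d < best[0] or (d == best[0] and (i, j) < best[1:]):
                    best = (d, i, j)
        d, i, j = best
        merged = ClusterNode(height=d, children=(nodes[i], nodes[j]))
        heights.append(d)
        nodes[next_id] = merged
        sizes[next_id] = sizes[i] + sizes[j]
        active = [a for a in active if a not in (i, j)]
        for a in active:
            dij = dist[tuple(sorted((a, i)))]
            djj = dist[tuple(sorted((a, j)))]
            if linkage == "complete":
                nd = max(dij, djj)
            elif linkage == "single":
                nd = min(dij, djj)
            else:  # average (UPGMA)
                nd = (dij * sizes[i] + djj * sizes[j]) / (sizes[i] + sizes[j])
            dist[(a, next_id)] = nd
        active.append(next_id)
        next_id += 1
    return Dendrogram(root=nodes[active[0]], labels=labels, merge_heights=heights)


def replicate_concordance(dendrogram: Dendrogram, sample_sheet: pd.DataFrame) -> float:
    """Fraction of (plasmid, gate) groups whose replicates form one clade.

    ``sample_sheet`` needs columns ``sample_id``, ``plasmid`` and ``gate``.
    A group is concordant when some dendrogram node's leaf set equals the
    group's sample set exactly (monophyly); singleton groups are trivially
    concordant.  Samples absent from the tree are ignored.
    """
    required = {"sample_id", "plasmid", "gate"}
    if not required <= set(sample_sheet.columns):
        raise ValueError(f"sample sheet needs columns {sorted(required)}")
    in_tree = set(dendrogram.labels)
    clades = set(dendrogram.clades())
    groups = sample_sheet[sample_sheet["sample_id"].isin(in_tree)].groupby(
        ["plasmid", "gate"]
    )["sample_id"]
    n_groups = 0
    n_ok = 0
    for _, ids in groups:
        n_groups += 1
        if frozenset(ids) in clades:
            n_ok += 1
    if n_groups == 0:
        raise ValueError("no sample-sheet groups overlap the dendrogram leaves")
    return n_ok / n_groups


def plot_heatmap(pattern: pd.DataFrame, dendrogram: Dendrogram, path) -> None:
    """Optional decoration: heatmap of the standardized pattern matrix with
    columns in dendrogram leaf order (red = under-, green = over-represented
    within its row)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = dendrogram.leaf_order()
    data = pattern[order].values
    fig, ax = plt.subplots(
        figsize=(max(4, 0.5 * len(order)), max(4, 0.01 * len(pattern)))
    )
    im = ax.imshow(data, aspect="auto", cmap="RdYlGn", interpolation="nearest")
    ax.set_xticks(range(len(order)))
    ax.set_xticklabels(order, rotation=90, fontsize=6)
    ax.set_yticks([])
    fig.colorbar(im, ax=ax, label="row z-score")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
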