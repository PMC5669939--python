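"""Log2 transformation and hierarchical clustering of expression profiles.

Samples are clustered on 1 - Pearson correlation across features with
average linkage (UPGMA on correlation distance).  The agglomeration is
implemented directly so that ties are broken deterministically by sample id,
making the tree invariant to feature and sample input order.  Trees
serialize to Newick.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "ClusterConfig",
    "ClusterNode",
    "log2_transform",
    "correlation_distance_matrix",
    "hierarchical_cluster",
    "replicate_coherence",
    "parse_newick",
    "plot_heatmap",
]

DEFAULT_PSEUDOCOUNT = 0.01


@dataclass(frozen=True)
class ClusterConfig:
    """pseudocount is in percent units; distance is 1 - Pearson; linkage is
    average (the only supported options are recorded for the manifest)."""

    pseudocount: float = DEFAULT_PSEUDOCOUNT
    distance: str = "pearson"
    linkage: str = "average"

    def __post_init__(self) -> None:
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")
        if self.distance != "pearson" or self.linkage != "average":
            raise ValueError("only distance='pearson', linkage='average' are supported")


def log2_transform(percents: pd.DataFrame, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> pd.DataFrame:
    """log2(percent + pseudocount); input values must be >= 0."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    if (percents.to_numpy() < 0).any():
        raise ValueError("negative expression values")
    return np.log2(percents + pseudocount)


@dataclass
class ClusterNode:
    """Binary tree node; leaves carry a sample id, internal nodes a merge height."""

    name: Optional[str] = None
    height: float = 0.0
    children: tuple["ClusterNode", "ClusterNode"] | tuple = field(default_factory=tuple)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        return [l for c in self.children for l in c.leaves()]

    def clades(self) -> list[frozenset[str]]:
        """Leaf sets of every node in the tree (including leaves and root)."""
        out = [frozenset(self.leaves())]
        for c in self.children:
            out.extend(c.clades())
        return out

    def to_newick(self) -> str:
        return self._newick_inner(parent_height=self.height) + ";"

    def _newick_inner(self, parent_height: float) -> str:
        length = max(parent_height - self.height, 0.0)
        if self.is_leaf:
            return f"{self.name}:{length:.6g}"
        inner = ",".join(c._newick_inner(self.height) for c in self.children)
        return f"({inner}):{length:.6g}"


def correlation_distance_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise 1 - Pearson distance between sample columns.

    A constant column has undefined correlation and raises, naming the sample.
    """
    X = matrix.to_numpy(dtype=float)
    sd = X.std(axis=0)
    constant = [c for c, s in zip(matrix.columns, sd) if s == 0]
    if constant:
        raise ValueError(f"constant expression column(s), correlation undefined: {constant}")
    corr = np.corrcoef(X, rowvar=False)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, 2.0)
    return pd.DataFrame(dist, index=matrix.columns, columns=matrix.columns)


def hierarchical_cluster(
    matrix: pd.DataFrame, config: ClusterConfig = ClusterConfig()
) -> ClusterNode:
    """Average-linkage agglomeration of sample columns on 1 - Pearson distance.

    At every step the pair of clusters at minimal distance merges; exact ties
    break by the lexicographically smallest pair of minimum leaf ids, so the
    result is independent of column order.  ``matrix`` is features x samples
    (already transformed, e.g. log2 percent).
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 samples to cluster")
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 features to cluster")
    dm = correlation_distance_matrix(matrix)
    # active clusters: key -> (node, size, min_leaf_id)
    nodes: dict[str, ClusterNode] = {s: ClusterNode(name=s) for s in dm.columns}
    sizes: dict[str, int] = {s: 1 for s in dm.columns}
    dist: dict[frozenset[str], float] = {}
    keys = sorted(nodes)
    for i, a in enumerate(keys):
        for b in keys[i + 1 :]:
            dist[frozenset((a, b))] = float(dm.loc[a, b])
    while len(nodes) > 1:
        active = sorted(nodes)
        best_pair = None
        best_d = None
        for i, a in enumerate(active):
            for b in active[i + 1 :]:
                d = dist[frozenset((a, b))]
                if best_d is None or d < best_d or (d == best_d and (a, b) < best_pair):
                    best_d = d
                    best_pair = (a, b)
        a, b = best_pair
        merged_key = min(a, b)  # representative: smallest leaf id in the cluster
        new_node = ClusterNode(height=best_d, children=(nodes[a], nodes[b]))
        na, nb = sizes[a], sizes[b]
        for c in active:
            if c in (a, b):
                continue
            d_new = (na * dist[frozenset((a, c))] + nb * dist[frozenset((b, c))]) / (na + nb)
            dist[frozenset((merged_key, c))] = d_new
        for c in (a, b):
            del nodes[c], sizes[c]
        nodes[merged_key] = new_node
        sizes[merged_key] = na + nb
    return next(iter(nodes.values()))


def replicate_coherence(tree: ClusterNode | str, sample_sheet: pd.DataFrame) -> dict[str, bool]:
    """Per-group: do the group's replicates form a clade of the sample tree?

    ``tree`` may be a :class:`ClusterNode` or a Newick string.  Every leaf
    must appear in the sample sheet and vice versa.
    """
    if isinstance(tree, str):
        tree = parse_newick(tree)
    leaves = set(tree.leaves())
    sheet_samples = set(sample_sheet["sample_id"])
    if leaves != sheet_samples:
        raise ValueError(
            f"tree leaves and sample sheet disagree: only in tree "
            f"{sorted(leaves - sheet_samples)}, only in sheet "
            f"{sorted(sheet_samples - leaves)}"
        )
    clades = set(tree.clades())
    out: dict[str, bool] = {}
    for g, sub in sample_sheet.groupby("group_id"):
        out[str(g)] = frozenset(sub["sample_id"]) in clades
    return out


def parse_newick(text: str) -> ClusterNode:
    """Parse a (binary, possibly multifurcating) Newick string into a ClusterNode.

    Branch lengths are accumulated into node heights relative to the deepest
    leaf; heights are only used for serialization round trips, the coherence
    test needs topology alone.
    """
    text = text.strip()
    if not text.endswith(";"):
        raise ValueError("Newick string must end with ';'")
    pos = 0
    s = text[:-1]

    def parse_node() -> tuple[ClusterNode, float]:
        nonlocal pos
        if pos < len(s) and s[pos] == "(":
            pos += 1
            children = []
            while True:
                child, _ = parse_node()
                children.append(child)
                if pos < len(s) and s[pos] == ",":
                    pos += 1
                    continue
                break
            if pos >= len(s) or s[pos] != ")":
                raise ValueError("unbalanced parentheses in Newick string")
            pos += 1
            name_start = pos
            while pos < len(s) and s[pos] not in ",();":
                pos += 1
            label = s[name_start:pos]
            length = 0.0
            if ":" in label:
                _, l = label.split(":", 1)
                length = float(l)
            node = ClusterNode(children=tuple(children))
            return node, length
        name_start = pos
        while pos < len(s) and s[pos] not in ",();":
            pos += 1
        token = s[name_start:pos]
        if ":" in token:
            name, l = token.split(":", 1)
            length = float(l)
        else:
            name, length = token, 0.0
        if not name:
            raise ValueError("empty leaf name in Newick string")
        return ClusterNode(name=name), length

    root, _ = parse_node()
    if pos != len(s):
        raise ValueError(f"trailing characters in Newick string: {s[pos:]!r}")

    def set_heights(node: ClusterNode) -> float:
        if node.is_leaf:
            node.height = 0.0
            return 0.0
        h = max(set_heights(c) for c in node.children)
        node.height = h
        return h

    set_heights(root)
    return root


def plot_heatmap(matrix: pd.DataFrame, path: str, cmap: str = "RdYlGn_r") -> None:
    """Basic log-expression heatmap (features x samples) saved to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(
        figsize=(max(4, 0.5 * matrix.shape[1]), max(4, 0.12 * matrix.shape[0]))
    )
    im = ax.imshow(matrix.to_numpy(), aspect="auto", cmap=cmap)
    ax.set_xticks(range(matrix.shape[1]))
    ax.set_xticklabels(matrix.columns, rotation=90, fontsize=6)
    ax.set_yticks([])
    fig.colorbar(im, ax=ax, label="log2 percent")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
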