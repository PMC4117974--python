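"""Median-Ks agglomerative clustering of a paralog group and neutral-rate dating.

The procedure treats every gene as its own cluster, repeatedly merges the
pair of clusters with the smallest between-cluster Ks — where the Ks
between multi-member clusters is the *median* over all cross pairs — and
records that median as the height of the merge node, until one cluster
remains.  Node heights (Ks values) convert to duplication dates through the
neutral molecular clock T = Ks / (2 * lambda), with lambda the synonymous
substitution rate per site per year (default 1.5e-8).

scipy's linkage methods do not implement this median-of-cross-pairs rule
(its "median" linkage is WPGMC on centroids), so the agglomeration is
implemented directly.

Numerical conventions: the median of an even-sized set is the mean of the
two middle values; undefined or infinite Ks entries are excluded from
medians, and a candidate merge whose cross pairs are all undefined is not
considered (if no merge is possible at some step, that is an error naming
the stranded clusters).  Ties on the smallest Ks are broken toward the
cluster pair whose lexicographically smallest member sorts first.  Median
linkage can produce height inversions (child above parent); node records
keep the raw heights, while Newick branch lengths are clamped at zero with
a warning.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

DEFAULT_RATE = 1.5e-8  # synonymous substitutions per site per year


@dataclass
class KsMatrix:
    """Symmetric pairwise-Ks matrix with a mask for undefined entries."""

    ids: list[str]
    values: np.ndarray  # (n, n) float
    defined: np.ndarray  # (n, n) bool

    @classmethod
    def from_pairs(
        cls, ids: Sequence[str], pairs: Mapping[frozenset, float | None]
    ) -> "KsMatrix":
        ids = list(ids)
        n = len(ids)
        values = np.zeros((n, n))
        defined = np.zeros((n, n), dtype=bool)
        np.fill_diagonal(defined, True)
        index = {g: i for i, g in enumerate(ids)}
        for key, ks in pairs.items():
            a, b = sorted(key)
            i, j = index[a], index[b]
            if ks is not None and math.isfinite(ks):
                if ks < 0:
                    raise ValueError(f"negative Ks for pair {a}-{b}")
                values[i, j] = values[j, i] = ks
                defined[i, j] = defined[j, i] = True
        return cls(ids, values, defined)


@dataclass
class ClusterNode:
    node_id: int
    height: float  # median Ks of the merge; 0.0 for leaves
    members: list[str]
    children: tuple[int, int] | None = None
    label: str = ""


@dataclass
class ClusterTree:
    """Binary merge tree; ``nodes[i]`` for i < n are leaves in input order."""

    nodes: list[ClusterNode]
    root: int

    def leaves(self) -> list[str]:
        return sorted(n.label for n in self.nodes if n.children is None)

    def internal_nodes(self) -> list[ClusterNode]:
        return [n for n in self.nodes if n.children is not None]


def _cross_median(
    ks: KsMatrix, cluster_a: Sequence[int], cluster_b: Sequence[int]
) -> float | None:
    values = [
        ks.values[i, j]
        for i in cluster_a
        for j in cluster_b
        if ks.defined[i, j]
    ]
    if not values:
        return None
    return float(np.median(values))


def median_ks_linkage(ks: KsMatrix) -> ClusterTree:
    """Agglomerate genes by smallest median cross-pair Ks.

    Every merge produces an internal node whose height is the median Ks of
    all cross pairs between the two merged clusters.
    """
    n = len(ks.ids)
    if n < 2:
        raise ValueError("need at least 2 genes to cluster")
    nodes = [ClusterNode(i, 0.0, [g], None, g) for i, g in enumerate(ks.ids)]
    # active clusters: node_id -> leaf indices
    active: dict[int, list[int]] = {i: [i] for i in range(n)}
    while len(active) > 1:
        best: tuple[float, str, str, int, int] | None = None
        for a in sorted(active):
            for b in sorted(active):
                if b <= a:
                    continue
                med = _cross_median(ks, active[a], active[b])
                if med is None:
                    continue
                key_a = min(nodes[a].members)
                key_b = min(nodes[b].members)
                lo_key, hi_key = sorted((key_a, key_b))
                candidate = (med, lo_key, hi_key, a, b)
                if best is None or candidate < best:
                    best = candidate
        if best is None:
            stranded = sorted(min(nodes[c].members) for c in active)
            raise ValueError(
                "no defined Ks between remaining clusters; stranded clusters "
                f"rooted at {stranded}"
            )
        med, _, _, a, b = best
        node_id = len(nodes)
        members = sorted(nodes[a].members + nodes[b].members)
        nodes.append(ClusterNode(node_id, med, members, (a, b)))
        active[node_id] = active.pop(a) + active.pop(b)
    return ClusterTree(nodes, root=len(nodes) - 1)


def date_duplication(ks: float, rate: float = DEFAULT_RATE) -> float:
    """Duplication age in years from Ks under a neutral clock: Ks / (2 * rate)."""
    if ks < 0:
        raise ValueError(f"negative Ks: {ks}")
    if rate <= 0:
        raise ValueError(f"rate must be positive, got {rate}")
    return ks / (2.0 * rate)


def to_newick(tree: ClusterTree) -> str:
    """Render the merge tree as Newick with heights as node depths.

    Branch length = parent height - child height, clamped at zero (with a
    warning) when median linkage inverts heights.  Children are ordered by
    their lexicographically smallest leaf.
    """
    clamped: list[str] = []

    def render(node_id: int, parent_height: float) -> str:
        node = tree.nodes[node_id]
        branch = parent_height - node.height
        if branch < 0:
            clamped.append(node.label or f"node{node.node_id}")
            branch = 0.0
        if node.children is None:
            return f"{node.label}:{_fmt(branch)}"
        kids = sorted(node.children, key=lambda c: min(tree.nodes[c].members))
        inner = ",".join(render(k, node.height) for k in kids)
        if node_id == tree.root:
            return f"({inner})"
        return f"({inner}):{_fmt(branch)}"

    root = tree.nodes[tree.root]
    kids = sorted(root.children, key=lambda c: min(tree.nodes[c].members))
    newick = "(" + ",".join(render(k, root.height) for k in kids) + ");"
    if clamped:
        warnings.warn(
            f"height inversion: clamped branch lengths to 0 above {clamped}",
            stacklevel=2,
        )
    return newick


def _fmt(x: float) -> str:
    return f"{x:.6g}"


def node_table(tree: ClusterTree, rate: float = DEFAULT_RATE) -> pd.DataFrame:
    """Internal-node table: members, median Ks (height) and dated age in years."""
    rows = []
    for node in tree.internal_nodes():
        rows.append(
            {
                "node_id": node.node_id,
                "members": ",".join(node.members),
                "median_ks": node.height,
                "date_years": date_duplication(node.height, rate),
            }
        )
    return pd.DataFrame(rows, columns=["node_id", "members", "median_ks", "date_years"])
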