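"""Phyletic-profile machinery: presence/absence matrices, Euclidean distances,
agglomerative clustering, Newick export, and discriminant-family extraction.

A phyletic matrix records, for each taxon and gene family, whether the taxon
has at least one protein assigned to the family (presence coding deliberately
ignores copy number).  Taxa are compared by the Euclidean distance between
their 0/1 rows — for binary vectors this is the square root of the Hamming
distance — and clustered agglomeratively.  Cutting the dendrogram at k
clusters recovers domain-level groupings; restricting columns to families
present in a focal group and extracting families on which a focal taxon
disagrees with the group majority yields the discriminant family sets.

Clustering is fully deterministic: among tied minimal-distance merges the
pair whose clusters carry the lexicographically smallest leaf labels is
merged first, and children of every node are ordered by smallest leaf label.
Matrices are plain :class:`pandas.DataFrame` objects (taxa as index, families
as columns); trees are :class:`DendrogramNode`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

LINKAGES = ("single", "complete", "average")


@dataclass(frozen=True)
class DendrogramNode:
    """A rooted binary merge tree; leaves have height 0 and carry the taxon."""

    height: float
    taxon: str | None = None
    children: tuple["DendrogramNode", "DendrogramNode"] | None = None

    @property
    def is_leaf(self) -> bool:
        return self.children is None

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.taxon]  # type: ignore[list-item]
        out: list[str] = []
        for c in self.children:  # type: ignore[union-attr]
            out.extend(c.leaves())
        return out

    def min_leaf(self) -> str:
        return min(self.leaves())


def leaf(taxon: str) -> DendrogramNode:
    return DendrogramNode(height=0.0, taxon=taxon)


def _merge(a: DendrogramNode, b: DendrogramNode, height: float) -> DendrogramNode:
    first, second = sorted((a, b), key=lambda n: n.min_leaf())
    return DendrogramNode(height=height, children=(first, second))


# ---------------------------------------------------------------------------
# matrix construction
# ---------------------------------------------------------------------------


def build_matrix(
    assignments: Mapping[str, "pd.DataFrame | Iterable[str]"],
    universe: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Binary taxa x family matrix: 1 iff the taxon has >=1 protein in the family.

    ``assignments`` maps each taxon either to a family table (a DataFrame with
    a ``family_id`` column) or to any iterable of family ids.  ``universe``
    fixes the column set (all-zero columns are retained); by default it is the
    union of observed families.
    """
    if not assignments:
        raise ValueError("at least one taxon is required")
    fams_by_taxon: dict[str, set[str]] = {}
    for taxon, val in assignments.items():
        if isinstance(val, pd.DataFrame):
            fams = set(val["family_id"].astype(str))
        else:
            fams = set(map(str, val))
        fams_by_taxon[str(taxon)] = fams
    if universe is None:
        columns = sorted(set().union(*fams_by_taxon.values()) if fams_by_taxon else set())
    else:
        columns = sorted(map(str, universe))
    taxa = sorted(fams_by_taxon)
    data = np.zeros((len(taxa), len(columns)), dtype="int8")
    col_idx = {f: j for j, f in enumerate(columns)}
    for i, t in enumerate(taxa):
        for f in fams_by_taxon[t]:
            j = col_idx.get(f)
            if j is not None:
                data[i, j] = 1
    return pd.DataFrame(data, index=taxa, columns=columns)


def euclidean_distances(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Euclidean distances between taxon rows.

    For 0/1 rows this equals the square root of the number of differing
    families (Hamming distance).
    """
    if len(matrix.index) < 2:
        raise ValueError("need at least two taxa")
    x = matrix.to_numpy(dtype=float)
    sq = (x * x).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (x @ x.T)
    np.fill_diagonal(d2, 0.0)
    d2 = np.clip(d2, 0.0, None)
    d = np.sqrt(d2)
    d = (d + d.T) / 2.0  # enforce exact symmetry
    return pd.DataFrame(d, index=matrix.index, columns=matrix.index)


# ---------------------------------------------------------------------------
# agglomerative clustering
# ---------------------------------------------------------------------------


def hierarchical_cluster(dist: pd.DataFrame, linkage: str = "complete") -> DendrogramNode:
    """Agglomerative clustering of a symmetric distance matrix.

    Repeatedly merges the pair of clusters at minimal linkage distance
    (single = minimum, complete = maximum, average = size-weighted mean of
    member distances, maintained by Lance-Williams updates); the merge height
    is that distance.  Exact ties are broken by the lexicographically
    smallest leaf labels of the candidate clusters, making the tree invariant
    to taxon input order.
    """
    if linkage not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}")
    taxa = [str(t) for t in dist.index]
    if len(taxa) < 2:
        raise ValueError("need at least two taxa to cluster")
    if list(dist.columns.astype(str)) != taxa:
        raise ValueError("distance matrix rows and columns must match")
    d = dist.to_numpy(dtype=float).copy()
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")

    n = len(taxa)
    nodes: dict[int, DendrogramNode] = {i: leaf(t) for i, t in enumerate(taxa)}
    sizes: dict[int, int] = {i: 1 for i in range(n)}
    keys: dict[int, str] = {i: t for i, t in enumerate(taxa)}  # min leaf label
    active = sorted(nodes)

    while len(active) > 1:
        # find minimal pairwise linkage distance among active clusters
        best_val = np.inf
        for ii, a in enumerate(active):
            row = d[a, active]
            row[ii] = np.inf
            m = row.min()
            if m < best_val:
                best_val = m
        # candidates tied at the minimum; pick lexicographically smallest labels
        best_pair: tuple[int, int] | None = None
        best_key: tuple[str, str] | None = None
        for ii, a in enumerate(active):
            for b in active[ii + 1 :]:
                if d[a, b] == best_val:
                    key = tuple(sorted((keys[a], keys[b])))
                    if best_key is None or key < best_key:
                        best_key = key  # type: ignore[assignment]
                        best_pair = (a, b)
        assert best_pair is not None
        a, b = best_pair
        merged = _merge(nodes[a], nodes[b], float(best_val))
        # Lance-Williams update of distances from the merged cluster (stored in slot a)
        for c in active:
            if c in (a, b):
                continue
            if linkage == "single":
                val = min(d[a, c], d[b, c])
            elif linkage == "complete":
                val = max(d[a, c], d[b, c])
            else:  # average (UPGMA)
                val = (sizes[a] * d[a, c] + sizes[b] * d[b, c]) / (sizes[a] + sizes[b])
            d[a, c] = d[c, a] = val
        nodes[a] = merged
        sizes[a] += sizes[b]
        keys[a] = min(keys[a], keys[b])
        del nodes[b], sizes[b], keys[b]
        active.remove(b)
    return nodes[active[0]]


# ---------------------------------------------------------------------------
# Newick serialization
# ---------------------------------------------------------------------------


def to_newick(tree: DendrogramNode, precision: int = 17) -> str:
    """Serialize the dendrogram; branch length = parent height - child height."""

    def fmt(x: float) -> str:
        return format(x, f".{precision}g")

    def render(node: DendrogramNode, parent_height: float) -> str:
        bl = fmt(parent_height - node.height)
        if node.is_leaf:
            return f"{node.taxon}:{bl}"
        inner = ",".join(render(c, node.height) for c in node.children)  # type: ignore[union-attr]
        return f"({inner}):{bl}"

    if tree.is_leaf:
        return f"{tree.taxon}:0;"
    inner = ",".join(render(c, tree.height) for c in tree.children)  # type: ignore[union-attr]
    return f"({inner});"


def from_newick(newick: str) -> DendrogramNode:
    """Parse a Newick string (as written by :func:`to_newick`) back to a tree.

    Heights are reconstructed from branch lengths assuming ultrametric leaves
    at height 0, which holds for every tree this module produces.
    """
    import dendropy

    t = dendropy.Tree.get(data=newick, schema="newick")

    def height(node) -> float:
        if node.is_leaf():
            return 0.0
        child = node.child_nodes()[0]
        return height(child) + (child.edge.length or 0.0)

    def convert(node) -> DendrogramNode:
        if node.is_leaf():
            return leaf(node.taxon.label.replace(" ", "_"))
        kids = [convert(c) for c in node.child_nodes()]
        if len(kids) != 2:
            raise ValueError("only binary trees are supported")
        return _merge(kids[0], kids[1], height(node))

    return convert(t.seed_node)


# ---------------------------------------------------------------------------
# tree cutting and discriminant families
# ---------------------------------------------------------------------------


def cut_clusters(tree: DendrogramNode, k: int) -> list[set[str]]:
    """Partition the taxa into ``k`` clusters by removing the k-1 highest merges.

    At each step the current root of maximal height is replaced by its two
    children (ties broken by height, then by smallest leaf label).  Returns
    the leaf sets sorted by smallest member.
    """
    n = len(tree.leaves())
    if not 1 <= k <= n:
        raise ValueError(f"k must lie in [1, {n}]")
    roots = [tree]
    for _ in range(k - 1):
        internal = [r for r in roots if not r.is_leaf]
        top = max(internal, key=lambda r: (r.height, r.min_leaf()))
        roots.remove(top)
        roots.extend(top.children)  # type: ignore[arg-type]
    parts = [set(r.leaves()) for r in roots]
    return sorted(parts, key=min)


def restrict_to_group(matrix: pd.DataFrame, group: Iterable[str]) -> pd.DataFrame:
    """Keep families present in at least one member of ``group``; keep all taxa."""
    group = [str(g) for g in group]
    if not group:
        raise ValueError("group must be non-empty")
    missing = set(group) - set(matrix.index.astype(str))
    if missing:
        raise ValueError("unknown taxa in group: " + ", ".join(sorted(missing)))
    keep = matrix.loc[group].sum(axis=0) >= 1
    return matrix.loc[:, keep]


def phyletic_differences(
    matrix: pd.DataFrame,
    taxon_a: str,
    taxon_b: str,
    family_subset: Iterable[str] | None = None,
) -> set[str]:
    """Families (within the subset) where the two taxa differ in presence."""
    for t in (taxon_a, taxon_b):
        if t not in matrix.index:
            raise ValueError(f"unknown taxon {t!r}")
    cols = list(matrix.columns) if family_subset is None else [str(f) for f in family_subset]
    missing = set(cols) - set(matrix.columns.astype(str))
    if missing:
        raise ValueError("unknown families in subset: " + ", ".join(sorted(missing)))
    if taxon_a == taxon_b:
        return set()
    sub = matrix.loc[[taxon_a, taxon_b], cols]
    diff = sub.loc[taxon_a] != sub.loc[taxon_b]
    return set(diff.index[diff])


def focal_discriminant(
    matrix: pd.DataFrame,
    focal: str,
    group: Iterable[str],
    majority: float = 0.5,
) -> set[str]:
    """Families separating a focal taxon from a group.

    Columns are first restricted to families present in ``group ∪ {focal}``;
    a family is discriminant when a strict majority (> ``majority`` fraction)
    of group members agree on a presence value and the focal taxon holds the
    opposite one.  Families with no strict group majority are excluded.
    """
    group = [str(g) for g in group]
    if not group:
        raise ValueError("group must be non-empty")
    if focal not in matrix.index:
        raise ValueError(f"unknown focal taxon {focal!r}")
    if focal in group:
        raise ValueError("group must exclude the focal taxon")
    restricted = restrict_to_group(matrix, group + [focal])
    out: set[str] = set()
    m = len(group)
    gsub = restricted.loc[group]
    ones = gsub.sum(axis=0)
    for fam in restricted.columns:
        s = int(ones[fam])
        if s / m > majority:
            consensus = 1
        elif (m - s) / m > majority:
            consensus = 0
        else:
            continue
        if int(restricted.loc[focal, fam]) != consensus:
            out.add(str(fam))
    return out


def leaf_order(tree: DendrogramNode) -> list[str]:
    """Left-to-right leaf order of the dendrogram (heatmap display order)."""
    return tree.leaves()


def order_by_clustering(
    matrix: pd.DataFrame, linkage: str = "complete"
) -> pd.DataFrame:
    """Reorder rows and columns by clustering each axis (heatmap layout).

    Rows are ordered by clustering taxa on their family profiles; columns by
    clustering families on their taxon profiles (the transpose).  Axes with a
    single label are left untouched.
    """
    out = matrix
    if len(matrix.index) >= 2:
        rows = leaf_order(hierarchical_cluster(euclidean_distances(matrix), linkage))
        out = out.loc[rows]
    if len(matrix.columns) >= 2:
        cols = leaf_order(hierarchical_cluster(euclidean_distances(matrix.T), linkage))
        out = out.loc[:, cols]
    return out
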