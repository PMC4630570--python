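"""Neighbor-joining phylogenetics with bootstrap support.

Protein p-distances with pairwise (or complete) deletion of gap columns,
Saitou-Nei neighbor joining with deterministic lexicographic tie-breaking,
and column-resampling bootstrap support with the classic ">50% displayed"
annotation rule.  Trees are dendropy objects, so newick I/O, bipartition
encoding and path-length queries come from that library.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np

__all__ = [
    "Alignment",
    "DistanceMatrix",
    "read_aligned_fasta",
    "pdistance_matrix",
    "nj_tree",
    "bootstrap_support",
    "tree_to_newick",
    "path_length_matrix",
]

GAP = "-"


@dataclass(frozen=True)
class Alignment:
    """Aligned amino-acid rows of equal length, gap symbol '-'."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if len(self.ids) != len(set(self.ids)):
            raise ValueError("duplicate sequence ids")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError(f"rows of unequal length: {sorted(lengths)}")
        if not self.rows or len(self.rows[0]) == 0:
            raise ValueError("empty alignment")

    @property
    def n_sites(self) -> int:
        return len(self.rows[0])

    def to_array(self) -> np.ndarray:
        return np.array([list(r) for r in self.rows])

    def resample_columns(self, rng: np.random.Generator) -> "Alignment":
        """Bootstrap replicate: sample columns with replacement."""
        cols = rng.integers(0, self.n_sites, size=self.n_sites)
        arr = self.to_array()[:, cols]
        return Alignment(self.ids, tuple("".join(row) for row in arr))


def read_aligned_fasta(path) -> Alignment:
    from Bio import SeqIO

    ids, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        rows.append(str(rec.seq).upper())
    return Alignment(tuple(ids), tuple(rows))


@dataclass(frozen=True)
class DistanceMatrix:
    ids: tuple[str, ...]
    values: np.ndarray  # symmetric, zero diagonal
    effective_sites: np.ndarray | None = None

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if (v < 0).any():
            raise ValueError("negative distances")
        if not np.allclose(np.diag(v), 0):
            raise ValueError("diagonal must be zero")


def pdistance_matrix(aln: Alignment, pairwise_deletion: bool = True) -> DistanceMatrix:
    """Proportion of differing sites per sequence pair.

    With pairwise deletion, only columns gapped in that particular pair are
    excluded; with complete deletion, columns gapped in any sequence are
    dropped for every pair.  A pair left with zero comparable sites is an
    error naming the pair.
    """
    if len(aln.ids) < 2:
        raise ValueError("need at least two sequences")
    arr = aln.to_array()
    gap = arr == GAP
    if not pairwise_deletion:
        keep = ~gap.any(axis=0)
        arr, gap = arr[:, keep], gap[:, keep]
    n = len(aln.ids)
    d = np.zeros((n, n))
    sites = np.zeros((n, n), dtype=int)
    np.fill_diagonal(sites, arr.shape[1])
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~(gap[i] | gap[j])
            m = int(ok.sum())
            if m == 0:
                raise ValueError(
                    f"no comparable sites between {aln.ids[i]!r} and {aln.ids[j]!r}"
                )
            diff = int((arr[i, ok] != arr[j, ok]).sum())
            d[i, j] = d[j, i] = diff / m
            sites[i, j] = sites[j, i] = m
    return DistanceMatrix(aln.ids, d, sites)


# ---------------------------------------------------------------------------
# neighbor joining


def _nj_nodes(ids: Sequence[str], taxa: dendropy.TaxonNamespace) -> list[dendropy.Node]:
    nodes = []
    for name in ids:
        node = dendropy.Node()
        node.taxon = taxa.get_taxon(name) or taxa.new_taxon(name)
        nodes.append(node)
    return nodes


def nj_tree(D: DistanceMatrix, taxon_namespace: dendropy.TaxonNamespace | None = None) -> dendropy.Tree:
    """Saitou-Nei neighbor joining.

    Iteratively joins the pair minimising Q(i,j) = (n-2) d(i,j) - r_i - r_j;
    ties (within 1e-12) break on the lexicographically smallest (id1, id2)
    pair, where a cluster is named after its smallest member leaf.  Negative
    branch-length estimates are clamped to zero with the deficit moved to the
    sibling branch.  Returns an unrooted dendropy tree whose seed node has
    degree 3.
    """
    n = len(D.ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least three taxa")
    taxa = taxon_namespace or dendropy.TaxonNamespace()
    nodes = _nj_nodes(D.ids, taxa)
    names = list(D.ids)  # cluster label = smallest member id (for tie-breaks)
    d = D.values.astype(float).copy()
    active = list(range(n))

    def clamp(pair: list[tuple[dendropy.Node, float]]) -> list[tuple[dendropy.Node, float]]:
        (na, la), (nb, lb) = pair
        if la < 0:
            lb, la = lb + la, 0.0
        if lb < 0:
            la, lb = la + lb, 0.0
        return [(na, max(la, 0.0)), (nb, max(lb, 0.0))]

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        best = None
        for a in range(m):
            for b in range(a + 1, m):
                if q[a, b] <= qmin + 1e-12:
                    key = tuple(sorted((names[active[a]], names[active[b]])))
                    if best is None or key < best[0]:
                        best = (key, a, b)
        _, a, b = best
        i, j = active[a], active[b]
        dij = d[i, j]
        li = 0.5 * dij + (r[a] - r[b]) / (2 * (m - 2))
        lj = dij - li
        parent = dendropy.Node()
        for child, length in clamp([(nodes[i], li), (nodes[j], lj)]):
            parent.add_child(child)
            child.edge.length = length
        new_index = len(nodes)
        nodes.append(parent)
        names.append(min(names[i], names[j]))
        newrow = np.zeros(new_index + 1)
        d = np.pad(d, ((0, 1), (0, 1)))
        for c in active:
            if c in (i, j):
                continue
            d[new_index, c] = d[c, new_index] = 0.5 * (d[i, c] + d[j, c] - dij)
        active = [c for c in active if c not in (i, j)] + [new_index]

    # connect the last three clusters through a central (seed) node
    i, j, k = active
    li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    center = dendropy.Node()
    for node, length in zip((nodes[i], nodes[j], nodes[k]), (li, lj, lk)):
        center.add_child(node)
        node.edge.length = max(length, 0.0)
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = center
    tree.is_rooted = False
    tree.update_bipartitions(suppress_unifurcations=False)
    return tree


def path_length_matrix(tree: dendropy.Tree, ids: Sequence[str]) -> np.ndarray:
    """Leaf-to-leaf patristic distances in the order of ``ids``."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(ids)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = pdm.patristic_distance(taxa[ids[i]], taxa[ids[j]])
    return out


# ---------------------------------------------------------------------------
# bootstrap


@dataclass
class SupportedTree:
    """Reference NJ tree plus bootstrap support (percent) per internal edge."""

    tree: dendropy.Tree
    supports: dict[frozenset, float] = field(default_factory=dict)
    n_reps: int = 0

    def newick(self, display_min_support: float = 50.0) -> str:
        """Newick with integer support labels; values <= the display floor
        are omitted (the classic "above 50%" figure convention)."""
        return tree_to_newick(self.tree, self.supports, display_min_support)


def _internal_bipartitions(tree: dendropy.Tree) -> dict[frozenset, dendropy.Node]:
    all_taxa = frozenset(t.label for t in tree.taxon_namespace)
    out: dict[frozenset, dendropy.Node] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if len(side) <= 1 or len(side) >= len(all_taxa) - 1:
            continue  # trivial split
        canonical = min(side, all_taxa - side, key=sorted)
        out[canonical] = node
    return out


def bootstrap_support(
    aln: Alignment,
    n_reps: int = 1000,
    seed: int = 0,
    pairwise_deletion: bool = True,
) -> SupportedTree:
    """NJ tree with column-bootstrap support on its internal bipartitions.

    Support = percentage of replicates (columns resampled with replacement,
    distances and NJ recomputed) whose tree contains the reference tree's
    bipartition.  Deterministic given the seed.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if len(aln.ids) < 4:
        raise ValueError("bootstrap support needs at least four taxa")
    rng = np.random.default_rng(seed)
    taxa = dendropy.TaxonNamespace()
    ref = nj_tree(pdistance_matrix(aln, pairwise_deletion), taxon_namespace=taxa)
    ref_bips = _internal_bipartitions(ref)
    counts = {bip: 0 for bip in ref_bips}
    for _ in range(n_reps):
        rep = aln.resample_columns(rng)
        rep_tree = nj_tree(pdistance_matrix(rep, pairwise_deletion), taxon_namespace=taxa)
        rep_bips = set(_internal_bipartitions(rep_tree))
        for bip in counts:
            if bip in rep_bips:
                counts[bip] += 1
    supports = {bip: 100.0 * c / n_reps for bip, c in counts.items()}
    for bip, node in ref_bips.items():
        node.label = str(int(round(supports[bip])))
    return SupportedTree(tree=ref, supports=supports, n_reps=n_reps)


def tree_to_newick(
    tree: dendropy.Tree,
    supports: Mapping[frozenset, float] | None = None,
    display_min_support: float | None = 50.0,
) -> str:
    """Newick string; optionally annotate internal nodes with support values,
    omitting any support <= ``display_min_support``."""
    if supports is not None:
        bips = _internal_bipartitions(tree)
        for bip, node in bips.items():
            s = supports.get(bip)
            show = s is not None and (display_min_support is None or s > display_min_support)
            node.label = str(int(round(s))) if show else None
    return tree.as_string(schema="newick", suppress_rooting=True).strip()
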