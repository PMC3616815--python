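"""Pairwise identity/substitution statistics, neighbour-joining trees and
subfamily assignment for gene families.

Distances are uncorrected p-distances with pairwise deletion: any column
where either sequence is gapped is excluded from both numerator and
denominator.  Trees come from the Saitou-Nei neighbour-joining
agglomeration (standard Q-criterion and branch-length formulas), with
deterministic lowest-index tie-breaking and negative branch-length
estimates clamped to zero with a warning.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import dendropy
import networkx as nx
import numpy as np
from Bio.Seq import Seq

from .records import Alignment, GAP

__all__ = ["DistanceMatrix", "pairwise_identity", "substitution_count",
           "translate", "p_distance_matrix", "nj_tree", "assign_subfamilies",
           "tree_to_graph"]


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("matrix not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("nonzero diagonal")
        if np.any(self.d < 0):
            raise ValueError("negative distances")

    def __len__(self) -> int:
        return len(self.labels)


def _comparable(a: str, b: str) -> tuple[np.ndarray, np.ndarray]:
    x = np.array(list(a.upper()))
    y = np.array(list(b.upper()))
    if len(x) != len(y):
        raise ValueError("sequences have unequal aligned length")
    keep = (x != GAP) & (y != GAP)
    return x[keep], y[keep]


def pairwise_identity(alignment: Alignment, id_i: str, id_j: str) -> float:
    """Percent identity over columns where neither record is gapped."""
    x, y = _comparable(alignment.record(id_i).residues,
                       alignment.record(id_j).residues)
    if len(x) == 0:
        raise ValueError(f"no comparable columns between {id_i} and {id_j}")
    return 100.0 * float(np.mean(x == y))


def substitution_count(alignment: Alignment, id_i: str, id_j: str) -> int:
    """Number of columns where both records are non-gap and differ."""
    x, y = _comparable(alignment.record(id_i).residues,
                       alignment.record(id_j).residues)
    return int(np.sum(x != y))


def translate(cds: str) -> str:
    """Translate a coding sequence with the standard code.

    Gaps are stripped first; the length must then be a multiple of 3.  A
    trailing stop is trimmed; an internal stop truncates the translation
    with a warning.
    """
    seq = cds.replace(GAP, "").upper()
    if len(seq) % 3 != 0:
        raise ValueError(f"cds length {len(seq)} not a multiple of 3")
    prot = str(Seq(seq).translate())
    if prot.endswith("*"):
        prot = prot[:-1]
    if "*" in prot:
        warnings.warn("internal stop codon; translation truncated")
        prot = prot.split("*")[0]
    return prot


def p_distance_matrix(alignment: Alignment) -> DistanceMatrix:
    """Pairwise p-distance (1 - identity/100) over all records."""
    labels = [r.record_id for r in alignment.records]
    n = len(labels)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        pid = pairwise_identity(alignment, labels[i], labels[j])
        d[i, j] = d[j, i] = 1.0 - pid / 100.0
    return DistanceMatrix(labels=labels, d=d)


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbour joining.

    Returns an unrooted binary tree (represented with a trifurcating
    root node, the newick convention for unrooted trees).  Ties in the
    Q-criterion break on the lowest (i, j) index pair; negative branch
    length estimates are clamped to 0 with a warning.
    """
    n = len(dm)
    if n < 3:
        raise ValueError("neighbour joining needs >= 3 taxa")
    taxa = dendropy.TaxonNamespace(dm.labels)
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes = []
    for lab in dm.labels:
        nd = dendropy.Node(taxon=taxa.get_taxon(lab))
        nodes.append(nd)
    D = dm.d.astype(float).copy()
    active = list(range(n))
    clamped = False

    def clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped = True
            return 0.0
        return x

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest-index tie-break: first minimum in row-major order
        flat = np.argmin(q)
        ai, aj = np.unravel_index(flat, q.shape)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = D[i, j]
        vi = clamp(0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2)))
        vj = clamp(dij - (0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))))
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = vi
        parent.add_child(nodes[j])
        nodes[j].edge.length = vj
        # distances from the new node to the remaining taxa
        new_row = 0.5 * (D[i, :] + D[j, :] - dij)
        D = np.vstack([D, new_row])
        new_col = np.append(new_row, 0.0)
        D = np.column_stack([D, new_col])
        nodes.append(parent)
        k = D.shape[0] - 1
        active = [a for a in active if a not in (i, j)] + [k]

    # join the final three nodes at an unresolved root
    a, b, c = active
    root = dendropy.Node()
    la = clamp(0.5 * (D[a, b] + D[a, c] - D[b, c]))
    lb = clamp(0.5 * (D[a, b] + D[b, c] - D[a, c]))
    lc = clamp(0.5 * (D[a, c] + D[b, c] - D[a, b]))
    for node, ln in ((nodes[a], la), (nodes[b], lb), (nodes[c], lc)):
        root.add_child(node)
        node.edge.length = ln
    if clamped:
        warnings.warn("negative neighbour-joining branch length(s) clamped to 0")
    tree.seed_node = root
    tree.is_rooted = False
    return tree


def tree_to_graph(tree: dendropy.Tree) -> tuple[nx.Graph, dict]:
    """Undirected weighted graph view of a dendropy tree.

    Returns the graph and a map node -> leaf label for leaf nodes.
    """
    g = nx.Graph()
    labels = {}
    for edge in tree.preorder_edge_iter():
        if edge.tail_node is None:
            continue
        g.add_edge(id(edge.tail_node), id(edge.head_node),
                   length=edge.length or 0.0)
    for leaf in tree.leaf_node_iter():
        labels[id(leaf)] = leaf.taxon.label
        g.add_node(id(leaf))
    return g, labels


def assign_subfamilies(tree: dendropy.Tree, k: int) -> dict[str, int]:
    """Partition leaves into ``k`` subfamilies by cutting the tree's
    ``k - 1`` longest internal branches.

    Components are numbered 1..k in order of their alphabetically first
    leaf.  Ties in branch length break deterministically on the sorted
    leaf-set bipartition.
    """
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(leaves):
        raise ValueError(f"k={k} exceeds leaf count {len(leaves)}")
    g, labels = tree_to_graph(tree)
    internal_edges = []
    for u, v, data in g.edges(data=True):
        if u in labels or v in labels:
            continue  # pendant edge
        # deterministic tiebreak key: leaves on the v-side of the edge
        h = g.copy()
        h.remove_edge(u, v)
        side = sorted(labels[x] for x in nx.node_connected_component(h, v)
                      if x in labels)
        internal_edges.append((data["length"], tuple(side), (u, v)))
    internal_edges.sort(key=lambda t: (-t[0], t[1]))
    cut = internal_edges[:k - 1]
    h = g.copy()
    for _, _, (u, v) in cut:
        h.remove_edge(u, v)
    comps = []
    for comp in nx.connected_components(h):
        members = sorted(labels[x] for x in comp if x in labels)
        if members:
            comps.append(members)
    # with k-1 internal cuts we get at most k leaf-bearing components; if
    # fewer internal edges exist than requested cuts, fall back to
    # singleton splitting of the largest components
    comps.sort(key=lambda ms: ms[0])
    while len(comps) < k:
        big = max(comps, key=len)
        if len(big) == 1:
            break
        comps.remove(big)
        comps.append([big[0]])
        comps.append(big[1:])
        comps.sort(key=lambda ms: ms[0])
    out = {}
    for idx, members in enumerate(comps, start=1):
        for mlabel in members:
            out[mlabel] = idx
    return out
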