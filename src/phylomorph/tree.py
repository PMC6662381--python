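"""Rooted time-calibrated phylogenies: reading, pruning, and Brownian-motion covariance.

Trees are stored in a flat array representation (parent pointers, edge
lengths, postorder) tuned for repeated likelihood evaluation and simulation.
Newick parsing and serialization are delegated to :mod:`dendropy`; everything
else operates on the arrays directly.

Node indexing convention: tips occupy indices ``0 .. n_tips-1`` (in the order
of ``tip_labels``); internal nodes follow; the root is always the last index.
"""

from __future__ import annotations

import io
import warnings
from typing import Iterable, Sequence

import dendropy
import numpy as np

__all__ = [
    "Phylogeny",
    "read_newick",
    "read_newick_trees",
    "write_newick",
    "prune_to_taxa",
    "phylo_covariance",
]


def _normalize_label(label: str) -> str:
    return "_".join(str(label).split())


class Phylogeny:
    """A rooted tree with nonnegative branch lengths in time units (Myr).

    Parameters
    ----------
    parent : array of int
        ``parent[i]`` is the parent node of ``i``; ``-1`` for the root.
    edge_length : array of float
        Length of the edge above each node; the root entry is ignored
        (kept as 0).
    tip_labels : sequence of str
        Labels for nodes ``0 .. n_tips-1``. Must be unique.
    """

    def __init__(self, parent, edge_length, tip_labels):
        self.parent = np.asarray(parent, dtype=np.int64)
        self.edge_length = np.asarray(edge_length, dtype=float)
        self.tip_labels = [str(t) for t in tip_labels]
        self.n_tips = len(self.tip_labels)
        self.n_nodes = len(self.parent)
        self._validate()
        self.root = int(np.flatnonzero(self.parent < 0)[0])
        self.children: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i in range(self.n_nodes):
            p = self.parent[i]
            if p >= 0:
                self.children[p].append(i)
        self.postorder = self._compute_postorder()
        self.preorder = self.postorder[::-1]

    # -- construction & validation -------------------------------------

    def _validate(self):
        if self.n_tips < 2:
            raise ValueError("a phylogeny needs at least 2 tips")
        if len(set(self.tip_labels)) != self.n_tips:
            dup = sorted({t for t in self.tip_labels if self.tip_labels.count(t) > 1})
            raise ValueError(f"duplicate tip labels: {dup}")
        if np.sum(self.parent < 0) != 1:
            raise ValueError("tree must have exactly one root")
        if np.any(self.edge_length[self.parent >= 0] < 0):
            raise ValueError("negative branch length")
        # reachability / acyclicity: every node must reach the root in
        # < n_nodes parent steps
        for i in range(self.n_nodes):
            j, steps = i, 0
            while self.parent[j] >= 0:
                j = self.parent[j]
                steps += 1
                if steps > self.n_nodes:
                    raise ValueError("cycle detected in parent pointers")

    def _compute_postorder(self) -> np.ndarray:
        order = []
        stack = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                order.append(node)
            else:
                stack.append((node, True))
                for c in self.children[node]:
                    stack.append((c, False))
        return np.asarray(order, dtype=np.int64)

    # -- basic queries ---------------------------------------------------

    def node_depths(self) -> np.ndarray:
        """Distance of every node from the root (root depth 0)."""
        depth = np.zeros(self.n_nodes)
        for node in self.preorder:
            p = self.parent[node]
            if p >= 0:
                depth[node] = depth[p] + self.edge_length[node]
        return depth

    @property
    def height(self) -> float:
        return float(self.node_depths()[: self.n_tips].max())

    @property
    def total_length(self) -> float:
        mask = self.parent >= 0
        return float(self.edge_length[mask].sum())

    def is_ultrametric(self, rtol: float = 1e-6) -> bool:
        d = self.node_depths()[: self.n_tips]
        h = d.max()
        return bool(h > 0 and (d.max() - d.min()) <= rtol * h)

    def tip_index(self, labels: Iterable[str]) -> np.ndarray:
        lut = {t: i for i, t in enumerate(self.tip_labels)}
        missing = [l for l in labels if _normalize_label(l) not in lut]
        if missing:
            raise KeyError(f"labels not in tree: {missing}")
        return np.asarray([lut[_normalize_label(l)] for l in labels], dtype=np.int64)

    def mrca(self, i: int, j: int) -> int:
        anc = set()
        a = i
        while a >= 0:
            anc.add(a)
            a = self.parent[a]
        a = j
        while a not in anc:
            a = self.parent[a]
        return int(a)

    def path_to_root(self, node: int) -> list[int]:
        out = [int(node)]
        while self.parent[out[-1]] >= 0:
            out.append(int(self.parent[out[-1]]))
        return out

    def descendant_tips(self) -> list[np.ndarray]:
        """Tip index set of the subtree below each node."""
        out: list[list[int] | np.ndarray] = [None] * self.n_nodes  # type: ignore
        for node in self.postorder:
            if node < self.n_tips:
                out[node] = np.asarray([node], dtype=np.int64)
            else:
                out[node] = np.concatenate([out[c] for c in self.children[node]])
        return out  # type: ignore

    def rescale(self, height: float) -> "Phylogeny":
        """Return a copy with branch lengths scaled so root-to-tip max equals *height*."""
        factor = height / self.height
        return Phylogeny(self.parent.copy(), self.edge_length * factor, list(self.tip_labels))

    # -- dendropy bridge -------------------------------------------------

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "Phylogeny":
        nodes = list(tree.preorder_node_iter())
        tips = [nd for nd in nodes if nd.is_leaf()]
        internals = [nd for nd in nodes if not nd.is_leaf()]
        # root last among internals
        internals = [nd for nd in reversed(internals)]
        index = {}
        labels = []
        for i, nd in enumerate(tips):
            raw = nd.taxon.label if nd.taxon is not None else nd.label
            if raw is None:
                raise ValueError("tip without a label")
            labels.append(_normalize_label(raw))
            index[id(nd)] = i
        for k, nd in enumerate(internals):
            index[id(nd)] = len(tips) + k
        n = len(nodes)
        parent = np.full(n, -1, dtype=np.int64)
        elen = np.zeros(n)
        for nd in nodes:
            i = index[id(nd)]
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
                if nd.edge.length is None:
                    raise ValueError(f"missing branch length above node {labels[i] if i < len(tips) else i}")
                elen[i] = float(nd.edge.length)
        return cls(parent, elen, labels)

    def to_dendropy(self) -> dendropy.Tree:
        taxa = dendropy.TaxonNamespace()
        tree = dendropy.Tree(taxon_namespace=taxa)
        dnodes = {}
        for node in self.preorder:
            nd = tree.seed_node if node == self.root else dendropy.Node()
            if self.parent[node] >= 0:
                dnodes[self.parent[node]].add_child(nd)
                nd.edge.length = float(self.edge_length[node])
            if node < self.n_tips:
                nd.taxon = taxa.new_taxon(self.tip_labels[node])
            dnodes[node] = nd
        return tree

    def __repr__(self):  # pragma: no cover - cosmetic
        return f"Phylogeny(n_tips={self.n_tips}, height={self.height:.4g})"


def read_newick(path_or_string) -> Phylogeny:
    """Read a single rooted Newick tree (file path, file object, or string)."""
    trees = read_newick_trees(path_or_string)
    if len(trees) != 1:
        raise ValueError(f"expected one tree, found {len(trees)}")
    return trees[0]


def read_newick_trees(path_or_string) -> list[Phylogeny]:
    """Read one or more Newick trees (e.g. a posterior chronogram set)."""
    if hasattr(path_or_string, "read"):
        data = path_or_string.read()
    else:
        s = str(path_or_string)
        if s.lstrip().startswith("("):
            data = s
        else:
            with open(s) as fh:
                data = fh.read()
    try:
        tl = dendropy.TreeList.get(data=data, schema="newick")
    except Exception as exc:  # dendropy raises several parser error types
        raise ValueError(f"malformed Newick: {exc}") from exc
    out = []
    for t in tl:
        phy = Phylogeny.from_dendropy(t)
        if not phy.is_ultrametric():
            warnings.warn("tree is not ultrametric within relative tolerance 1e-6")
        out.append(phy)
    return out


def write_newick(tree: Phylogeny, path=None) -> str:
    s = tree.to_dendropy().as_string(schema="newick", suppress_rooting=True)
    s = s.strip() + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(s)
    return s


def prune_to_taxa(tree: Phylogeny, keep: Iterable[str]) -> Phylogeny:
    """Restrict *tree* to the tips in *keep*.

    Degree-2 internal nodes produced by pruning are collapsed with their edge
    lengths summed, so root-to-tip distances of retained tips are unchanged.
    """
    keep_norm = [_normalize_label(k) for k in keep]
    keep_set = set(keep_norm)
    missing = sorted(keep_set - set(tree.tip_labels))
    if missing:
        raise KeyError(f"labels not in tree: {missing}")
    if len(keep_set) < 2:
        raise ValueError("need at least 2 taxa to keep")

    # count retained tips under each node
    n_kept = np.zeros(tree.n_nodes, dtype=np.int64)
    keep_tip = np.zeros(tree.n_nodes, dtype=bool)
    for i, lab in enumerate(tree.tip_labels):
        if lab in keep_set:
            keep_tip[i] = True
    for node in tree.postorder:
        if node < tree.n_tips:
            n_kept[node] = int(keep_tip[node])
        else:
            n_kept[node] = sum(n_kept[c] for c in tree.children[node])

    # retained structural nodes: kept tips, and internal nodes with >= 2
    # children whose subtrees contain kept tips (the new root is the deepest
    # such node)
    retained_children = {
        node: [c for c in tree.children[node] if n_kept[c] > 0] for node in range(tree.n_nodes)
    }
    structural = np.zeros(tree.n_nodes, dtype=bool)
    for node in range(tree.n_nodes):
        if keep_tip[node] or (node >= tree.n_tips and len(retained_children[node]) >= 2):
            structural[node] = True

    # new root = structural node closest to old root on the retained spine
    new_root_old = None
    for node in tree.preorder:
        if structural[node]:
            new_root_old = int(node)
            break
    assert new_root_old is not None

    new_tips = [lab for lab in tree.tip_labels if lab in keep_set]
    # map old structural nodes to new indices: tips first (tree order), then
    # internals in reverse-preorder so the root lands last
    tip_map = {}
    k = 0
    for i, lab in enumerate(tree.tip_labels):
        if keep_tip[i]:
            tip_map[i] = k
            k += 1
    internal_old = [n for n in tree.preorder if structural[n] and n >= tree.n_tips]
    # make sure the new root is last
    internal_new_order = list(reversed(internal_old))
    node_map = dict(tip_map)
    for j, n in enumerate(internal_new_order):
        node_map[n] = len(new_tips) + j

    n_new = len(node_map)
    parent = np.full(n_new, -1, dtype=np.int64)
    elen = np.zeros(n_new)
    for old in node_map:
        if old == new_root_old:
            continue
        # walk up through collapsed degree-1 nodes, summing lengths
        length = tree.edge_length[old]
        p = tree.parent[old]
        while p >= 0 and not structural[p]:
            length += tree.edge_length[p]
            p = tree.parent[p]
        if p < 0 or old == new_root_old:
            continue
        # ancestors above the new root are ignored
        if p not in node_map:
            continue
        parent[node_map[old]] = node_map[p]
        elen[node_map[old]] = length
    # anything that walked past new_root_old gets parent -1 — only the root may
    if np.sum(parent < 0) != 1:
        raise RuntimeError("pruning produced a malformed tree")
    return Phylogeny(parent, elen, new_tips)


def phylo_covariance(tree: Phylogeny, taxa: Sequence[str] | None = None):
    """Brownian-motion covariance among tips: shared path length from the root.

    Returns ``(matrix, taxon_order)``. ``matrix[i, i]`` is tip *i*'s
    root-to-tip distance and ``matrix[i, j]`` the depth of ``MRCA(i, j)``.
    """
    depth = tree.node_depths()
    n = tree.n_tips
    C = np.zeros((n, n))
    desc = tree.descendant_tips()
    for node in tree.postorder:
        if node < tree.n_tips:
            continue
        kids = tree.children[node]
        for a in range(len(kids)):
            for b in range(a + 1, len(kids)):
                ta, tb = desc[kids[a]], desc[kids[b]]
                C[np.ix_(ta, tb)] = depth[node]
                C[np.ix_(tb, ta)] = depth[node]
    np.fill_diagonal(C, depth[:n])
    order = list(tree.tip_labels)
    if taxa is not None:
        idx = tree.tip_index(taxa)
        C = C[np.ix_(idx, idx)]
        order = [tree.tip_labels[i] for i in idx]
    return C, order
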