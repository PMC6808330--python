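"""Rooted phylogenies: Newick I/O, outgroup pruning, and an indexed view.

Trees are consumed as upstream products (inference is out of scope here);
dendropy does the parsing.  :class:`PhyloTree` wraps a dendropy tree and
adds the array-indexed structure the Poisson-tree-processes machinery needs:
postorder node lists, parent pointers, per-edge lengths and per-subtree
edge-length sums.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np

from .exceptions import InputError, UnrootedTreeError


class PhyloTree:
    """A rooted tree with branch lengths and optional node support values.

    Node support (e.g. Bayesian posterior probabilities written as internal
    node labels in the Newick string) is parsed when numeric.
    """

    def __init__(self, tree: dendropy.Tree, require_rooted: bool = True) -> None:
        root = tree.seed_node
        if require_rooted and len(root.child_nodes()) > 2:
            raise UnrootedTreeError(
                "root has more than two children; pass allow_unrooted=True "
                "to accept the tree as rooted at this node"
            )
        self._tree = tree
        self._index()

    # ----------------------------------------------------------- indexing
    def _index(self) -> None:
        nodes = list(self._tree.postorder_node_iter())
        self._nodes = nodes
        self._id = {id(nd): i for i, nd in enumerate(nodes)}
        n = len(nodes)
        self.parent = np.full(n, -1, dtype=int)
        self.edge_len = np.zeros(n, dtype=float)
        self.children: list[list[int]] = [[] for _ in range(n)]
        self.label: list[str | None] = [None] * n
        self.support: list[float | None] = [None] * n
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                p = self._id[id(nd.parent_node)]
                self.parent[i] = p
                self.children[p].append(i)
                self.edge_len[i] = float(nd.edge.length or 0.0)
            if nd.taxon is not None:
                self.label[i] = nd.taxon.label
            elif nd.label is not None:
                try:
                    self.support[i] = float(nd.label)
                except ValueError:
                    self.label[i] = nd.label
        self.root = self._id[id(self._tree.seed_node)]
        self.is_tip = np.array([len(c) == 0 for c in self.children])
        # tips below each node, and edge-length sums strictly below each node
        self.n_tips_below = np.zeros(n, dtype=int)
        self.sum_below = np.zeros(n, dtype=float)
        self.cnt_below = np.zeros(n, dtype=int)
        for i in range(n):  # postorder: children precede parents
            if self.is_tip[i]:
                self.n_tips_below[i] = 1
            for c in self.children[i]:
                self.n_tips_below[i] += self.n_tips_below[c]
                self.sum_below[i] += self.sum_below[c] + self.edge_len[c]
                self.cnt_below[i] += self.cnt_below[c] + 1

    # ----------------------------------------------------------- properties
    @property
    def tips(self) -> list[str]:
        return [self.label[i] for i in range(len(self._nodes)) if self.is_tip[i]]

    @property
    def n_tips(self) -> int:
        return int(self.is_tip.sum())

    @property
    def n_nodes(self) -> int:
        return len(self._nodes)

    @property
    def n_branches(self) -> int:
        """Every node except the root carries the branch to its parent."""
        return self.n_nodes - 1

    @property
    def branch_lengths(self) -> np.ndarray:
        """Lengths of all branches (indexed by child node; root excluded)."""
        mask = np.ones(self.n_nodes, dtype=bool)
        mask[self.root] = False
        return self.edge_len[mask]

    def tip_index(self) -> dict[str, int]:
        return {self.label[i]: i for i in range(self.n_nodes) if self.is_tip[i]}

    def tipset_below(self, node: int) -> frozenset[str]:
        out: list[str] = []
        stack = [node]
        while stack:
            v = stack.pop()
            if self.is_tip[v]:
                out.append(self.label[v])
            stack.extend(self.children[v])
        return frozenset(out)

    def mrca(self, taxa: Iterable[str]) -> int:
        idx = self.tip_index()
        try:
            nodes = [idx[t] for t in taxa]
        except KeyError as e:
            raise InputError(f"unknown taxon {e.args[0]!r}") from None
        if not nodes:
            raise InputError("empty taxon set")
        # walk each tip's ancestor path; intersect
        paths = []
        for v in nodes:
            path = []
            while v != -1:
                path.append(v)
                v = self.parent[v]
            paths.append(path)
        common = set(paths[0])
        for p in paths[1:]:
            common &= set(p)
        # deepest common ancestor = first on any path that is common
        for v in paths[0]:
            if v in common:
                return v
        raise InputError("disconnected tips")  # pragma: no cover

    def is_monophyletic(self, taxa: Iterable[str]) -> bool:
        taxa = frozenset(taxa)
        return self.tipset_below(self.mrca(taxa)) == taxa

    def node_support(self, node: int) -> float | None:
        return self.support[node]

    def as_newick(self) -> str:
        return self._tree.as_string(schema="newick", suppress_rooting=True).strip()

    def clone(self) -> "PhyloTree":
        return PhyloTree(self._tree.clone(depth=1), require_rooted=False)


def read_newick(
    source: str | Path,
    allow_unrooted: bool = False,
) -> PhyloTree:
    """Read a Newick tree from a file path or a literal Newick string."""
    text = None
    if isinstance(source, Path) or (isinstance(source, str) and not source.lstrip().startswith("(")):
        text = Path(source).read_text()
    else:
        text = str(source)
    tree = dendropy.Tree.get(
        data=text,
        schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    return PhyloTree(tree, require_rooted=not allow_unrooted)


def prune_taxa(tree: PhyloTree, taxa: Sequence[str]) -> PhyloTree:
    """Remove tips, suppressing the resulting degree-2 nodes (their branch
    lengths are summed onto the retained child branch)."""
    known = set(tree.tips)
    missing = [t for t in taxa if t not in known]
    if missing:
        raise InputError(f"cannot prune unknown taxa: {missing}")
    dtree = tree._tree.clone(depth=1)
    drop = [l.taxon for l in dtree.leaf_node_iter() if l.taxon.label in set(taxa)]
    dtree.prune_taxa(drop)
    return PhyloTree(dtree, require_rooted=False)
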